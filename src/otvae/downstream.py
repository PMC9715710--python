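"""Downstream uses of a trained model and transport plan.

* cross-dataset gene imputation: encode a source dataset's common genes and
  decode through the *target* dataset's branches, yielding the target's
  common and specific gene values for every source cell;
* label transfer / spot deconvolution: the (cell x target) transport plan is
  column-normalized into a probabilistic correspondence, aggregated over
  source labels;
* TLS (tertiary lymphoid structure) scoring: per-spot sum of T-cell and
  B-cell proportions with a colocalization flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CoupledVAE


def impute(
    model: CoupledVAE,
    source_common: np.ndarray,
    source_id: str,
    target_id: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict the target dataset's common and specific genes for source cells.

    Deterministic: encodes in eval mode, decodes z = mu through the target's
    DSBN branch and specific decoder. Imputing a dataset into itself
    reproduces its own reconstruction. Works on cells never seen in training
    (online imputation) since no retraining is involved.
    """
    for ds in (source_id, target_id):
        model._require_dataset(ds)
    z = model.encode(np.asarray(source_common)).mu
    common_hat = model.decode_common(z, target_id)
    specific_hat = model.decode_specific(z, target_id)
    return common_hat, specific_hat


@dataclass
class LabelTransferResult:
    """Per-target-cell class probabilities and hard labels from the plan."""

    probabilities: pd.DataFrame  # target cells x classes, rows sum to 1
    labels: pd.Series            # argmax class, NaN for zero-mass targets
    zero_mass: np.ndarray        # flag: column of the plan had no mass
    ties: np.ndarray             # flag: argmax was tied (first lexicographic kept)


def label_transfer(plan: np.ndarray, source_labels, target_ids=None) -> LabelTransferResult:
    """Transfer source labels through the transport plan.

    For target j, P(class c | j) = sum_{i: label_i = c} T_ij / sum_i T_ij.
    Invariant to global rescaling of the plan. Zero-mass columns are flagged
    and receive no label.
    """
    T = np.asarray(plan, dtype=np.float64)
    source_labels = np.asarray(source_labels)
    if T.ndim != 2 or T.shape[0] != len(source_labels):
        raise ValueError(
            f"plan has {T.shape[0]} rows but {len(source_labels)} source labels"
        )
    if np.any(T < 0):
        raise ValueError("transport plan must be non-negative")
    classes = sorted(set(source_labels))
    if target_ids is None:
        target_ids = [f"target{j}" for j in range(T.shape[1])]
    mass = np.stack([T[source_labels == c].sum(axis=0) for c in classes], axis=1)
    col_mass = mass.sum(axis=1)
    zero = col_mass <= 0
    probs = np.zeros_like(mass)
    probs[~zero] = mass[~zero] / col_mass[~zero, None]
    best = probs.argmax(axis=1)
    ties = (probs == probs[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    labels = pd.Series(
        [classes[b] if not z else np.nan for b, z in zip(best, zero)],
        index=list(target_ids), name="label",
    )
    prob_df = pd.DataFrame(probs, index=list(target_ids), columns=classes)
    return LabelTransferResult(probabilities=prob_df, labels=labels,
                               zero_mass=zero, ties=ties & ~zero)


@dataclass
class DeconvolutionResult:
    """Spot-by-celltype proportions; rows sum to 1 except flagged zero-mass spots."""

    proportions: pd.DataFrame
    zero_mass: np.ndarray

    def __post_init__(self):
        P = self.proportions.to_numpy()
        ok = ~self.zero_mass
        if ok.any() and not np.allclose(P[ok].sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("spot proportions must sum to 1")


def deconvolute(plan: np.ndarray, source_labels, spot_ids=None) -> DeconvolutionResult:
    """Estimate per-spot cell-type proportions from the cell-to-spot plan.

    Identical computation to :func:`label_transfer`; the columns of the plan
    are spatial spots and the probability vectors are the proportions.
    """
    lt = label_transfer(plan, source_labels, target_ids=spot_ids)
    return DeconvolutionResult(proportions=lt.probabilities, zero_mass=lt.zero_mass)


def tls_score(
    result: DeconvolutionResult,
    t_cell_label: str,
    b_cell_label: str,
    colocalization_floor: float = 0.05,
) -> pd.DataFrame:
    """Per-spot TLS score: summed T-cell and B-cell proportions.

    A spot is flagged colocalized when both proportions individually exceed
    ``colocalization_floor``. Scores lie in [0, 1].
    """
    P = result.proportions
    for lab in (t_cell_label, b_cell_label):
        if lab not in P.columns:
            raise KeyError(f"label {lab!r} not present in the deconvolution result")
    t = P[t_cell_label].to_numpy()
    b = P[b_cell_label].to_numpy()
    return pd.DataFrame(
        {
            "tls_score": t + b,
            "colocalized": (t > colocalization_floor) & (b > colocalization_floor),
        },
        index=P.index,
    )
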