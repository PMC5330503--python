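"""Three-way mechanistic classification and disorder prediction from max RMSD.

Classes are defined from where disorder appears relative to the max-RMSD
pair of each protein:

* ``rigid`` — no conformer has an IDR;
* ``partially_disordered`` — IDRs exist and at least one conformer of the
  max-RMSD pair has one;
* ``malleable`` — IDRs exist but the max-RMSD pair is fully ordered.

The labels are mutually exclusive and exhaustive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from confdiv.disorder import IDRAnnotation
from confdiv.io import EnsembleRecord
from confdiv.superpose import MaxPair

__all__ = ["ClassLabel", "classify_protein", "evaluate_disorder_predictor", "CLASS_NAMES"]

CLASS_NAMES = ("rigid", "partially_disordered", "malleable")


@dataclass(frozen=True)
class ClassLabel:
    protein_id: str
    label: str
    max_pair: MaxPair
    has_idr_any_conformer: bool
    has_idr_in_max_pair: bool


def classify_protein(
    ens: EnsembleRecord, idrs: Sequence[IDRAnnotation], max_pair: MaxPair
) -> ClassLabel:
    """Deterministic class label from the IDR evidence and the max-RMSD pair.

    An IDR "in the max pair" means at least one of the two max-pair
    conformers has at least one IDR.
    """
    by_id = {a.conformer_id: a for a in idrs}
    missing = {c.conformer_id for c in ens.conformers} - set(by_id)
    if missing:
        raise ValueError(f"{ens.protein_id}: no IDR annotation for {sorted(missing)}")
    has_any = any(a.has_idr for a in idrs)
    in_pair = any(by_id[cid].has_idr for cid in max_pair.pair)
    if not has_any:
        label = "rigid"
    elif in_pair:
        label = "partially_disordered"
    else:
        label = "malleable"
    return ClassLabel(ens.protein_id, label, max_pair, has_any, in_pair)


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank statistic (Mann-Whitney U / (n1*n0)); ties get half credit."""
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # average ranks under ties
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def evaluate_disorder_predictor(
    max_rmsds: Sequence[float],
    labels: Sequence[bool],
    cutoffs: Sequence[float] = (0.9, 1.2),
) -> dict:
    """Evaluate max RMSD as a predictor of protein-level disorder.

    ``labels`` marks proteins with at least one IDR-bearing conformer.
    Returns the ROC AUC (rank statistic), accuracy at each cutoff
    (predict disordered iff max RMSD > c), two enrichment readings at each
    cutoff, and a logistic-regression coefficient with its Wald p-value.

    Enrichment is reported twice because its arithmetic can be read two
    ways: ``enrichment_ratio_at`` is the odds-ratio form
    ((D>c)/(D<=c)) / ((O>c)/(O<=c)); ``disordered_above_below_ratio_at`` is
    the raw count form (D>c)/(D<=c) for the disordered proteins alone.
    """
    scores = np.asarray(max_rmsds, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC is undefined with a single class")
    out: dict = {"auc": _auc_rank(scores, y), "n_disordered": n1, "n_ordered": n0}

    acc, enrich, raw = {}, {}, {}
    for c in cutoffs:
        pred = scores > c
        acc[c] = float((pred == y).mean())
        d_above, d_below = int((y & pred).sum()), int((y & ~pred).sum())
        o_above, o_below = int((~y & pred).sum()), int((~y & ~pred).sum())
        raw[c] = d_above / d_below if d_below else np.inf
        if o_above and d_below and o_below:
            enrich[c] = (d_above / o_above) / (d_below / o_below)
        else:
            enrich[c] = np.inf if d_above else np.nan
    out["accuracy_at"] = acc
    out["enrichment_ratio_at"] = enrich
    out["disordered_above_below_ratio_at"] = raw

    # logistic regression of label on max RMSD (IRLS), Wald p-value
    X = sm.add_constant(scores)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation emits benign warnings
            fit = sm.Logit(y.astype(float), X).fit(disp=0, maxiter=200)
        out["logit_coef"] = float(fit.params[1])
        out["logit_p"] = float(fit.pvalues[1])
        out["logit_separation"] = bool(not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e6)
    except Exception:  # perfect separation or non-convergence
        out["logit_coef"] = np.inf
        out["logit_p"] = np.nan
        out["logit_separation"] = True
    return out


def labels_to_frame(labels: Sequence[ClassLabel]):
    import pandas as pd

    return pd.DataFrame(
        {
            "protein_id": [l.protein_id for l in labels],
            "label": [l.label for l in labels],
            "max_rmsd": [l.max_pair.rmsd for l in labels],
            "max_pair_a": [l.max_pair.pair[0] for l in labels],
            "max_pair_b": [l.max_pair.pair[1] for l in labels],
            "has_idr_any_conformer": [l.has_idr_any_conformer for l in labels],
            "has_idr_in_max_pair": [l.has_idr_in_max_pair for l in labels],
        }
    )
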