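"""Intrinsic disorder from missing electron density.

A residue with missing coordinates in an X-ray structure is taken to be
disordered.  An intrinsically disordered region (IDR) is a run of five or
more consecutive missing residues lying outside the terminal windows (the
first and last twenty positions of the deposited sequence): termini are
routinely unresolved for reasons unrelated to intrinsic disorder.

A run that straddles a terminal window is, by default, truncated to its
interior portion and re-tested against the five-residue threshold
(``terminal_run_policy="truncate"``); the stricter alternative of discarding
such runs entirely is available as ``"discard"``.

The module also provides the amino-acid composition profile of disordered
regions against a reference composition, with bootstrap confidence
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from confdiv.io import ConformerStructure, EnsembleRecord

__all__ = [
    "IDRAnnotation",
    "CompositionProfile",
    "detect_idrs",
    "ensemble_disorder_summary",
    "composition_profile",
    "idr_residue_counts",
    "load_reference_frequencies",
]

TERMINAL_WINDOW = 20
MIN_IDR_LENGTH = 5

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class IDRAnnotation:
    conformer_id: str
    segments: list[tuple[int, int]]  # closed intervals, disjoint, sorted
    disorder_fraction: float  # total segment length / sequence_length
    sequence_length: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def has_idr(self) -> bool:
        return bool(self.segments)

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for s, e in self.segments)

    def positions(self) -> set[int]:
        out: set[int] = set()
        for s, e in self.segments:
            out.update(range(s, e + 1))
        return out


def _missing_runs(conf: ConformerStructure) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    start = None
    prev = None
    for r in conf.residues:
        if not r.observed:
            if start is None:
                start = r.seq_pos
            prev = r.seq_pos
        else:
            if start is not None:
                runs.append((start, prev))
                start = None
    if start is not None:
        runs.append((start, prev))
    return runs


def detect_idrs(
    conf: ConformerStructure,
    terminal_window: int = TERMINAL_WINDOW,
    min_length: int = MIN_IDR_LENGTH,
    terminal_run_policy: str = "truncate",
    fraction_denominator: str = "full",
) -> IDRAnnotation:
    """Detect IDRs of one conformer from its observed/unobserved flags.

    Depends only on the observed flags, never on coordinates.  Sequences of
    40 or fewer residues have no interior window and yield an empty,
    flagged annotation.
    """
    if terminal_run_policy not in ("truncate", "discard"):
        raise ValueError(f"unknown terminal_run_policy {terminal_run_policy!r}")
    L = conf.sequence_length
    flags: list[str] = []
    if L <= 2 * terminal_window:
        return IDRAnnotation(conf.conformer_id, [], 0.0, L, ["sequence_too_short"])
    first = conf.residues[0].seq_pos if conf.residues else 1
    lo, hi = first + terminal_window, first + L - 1 - terminal_window  # interior, closed
    segments: list[tuple[int, int]] = []
    for start, end in _missing_runs(conf):
        if terminal_run_policy == "discard" and (start < lo or end > hi):
            continue
        s, e = max(start, lo), min(end, hi)
        if e - s + 1 >= min_length:
            segments.append((s, e))
    if fraction_denominator == "full":
        denom = L
    elif fraction_denominator == "observed":
        denom = max(conf.n_observed, 1)
    else:
        raise ValueError(f"unknown fraction_denominator {fraction_denominator!r}")
    total = sum(e - s + 1 for s, e in segments)
    return IDRAnnotation(conf.conformer_id, segments, total / denom, L, flags)


def ensemble_disorder_summary(
    ens: EnsembleRecord, idrs: Sequence[IDRAnnotation]
) -> dict:
    """Per-protein disorder summary over all conformers.

    Returns percent of conformers with at least one IDR, the maximum
    disorder fraction, the longest IDR length and the number of
    order/disorder transition positions (inside an IDR in at least one
    conformer *and* observed in at least one conformer).
    """
    if len(idrs) != ens.n_conformers:
        raise ValueError("need exactly one IDR annotation per conformer")
    n = ens.n_conformers
    n_dis = sum(1 for a in idrs if a.has_idr)
    max_frac = max((a.disorder_fraction for a in idrs), default=0.0)
    longest = max((e - s + 1 for a in idrs for s, e in a.segments), default=0)
    idr_positions: set[int] = set()
    for a in idrs:
        idr_positions |= a.positions()
    observed_somewhere = set(ens.correspondence)
    transitions = idr_positions & observed_somewhere
    return {
        "protein_id": ens.protein_id,
        "n_conformers": n,
        "n_disordered_conformers": n_dis,
        "percent_disordered_conformers": 100.0 * n_dis / n,
        "max_disorder_fraction": max_frac,
        "longest_idr_length": longest,
        "n_transition_positions": len(transitions),
    }


# ---------------------------------------------------------------------------
# composition profile
# ---------------------------------------------------------------------------


@dataclass
class CompositionProfile:
    """Per-amino-acid enrichment of a query set relative to a reference.

    enrichment_aa = (f_query - f_ref) / f_ref, with a percentile bootstrap
    95% confidence interval obtained by resampling the query residues with
    replacement (the reference is treated as fixed).
    """

    table: pd.DataFrame  # index: aa; columns: enrichment, ci_low, ci_high, f_query, f_ref
    n_boot: int
    flags: list[str] = field(default_factory=list)

    def enrichment(self, aa: str) -> float:
        return float(self.table.loc[aa, "enrichment"])


def composition_profile(
    query_counts: Mapping[str, int],
    ref_freqs: Mapping[str, float],
    n_boot: int = 10_000,
    seed: int = 0,
    ci: float = 0.95,
) -> CompositionProfile:
    """Composition profile of a residue set against a reference composition."""
    aas = [aa for aa in AMINO_ACIDS if aa in ref_freqs or aa in query_counts]
    counts = np.array([float(query_counts.get(aa, 0)) for aa in aas])
    total = counts.sum()
    if total <= 0:
        raise ValueError("query has no residues")
    ref = np.array([float(ref_freqs.get(aa, 0.0)) for aa in aas])
    if not np.isclose(ref.sum(), 1.0, atol=1e-3):
        raise ValueError(f"reference frequencies sum to {ref.sum():.4f}, expected 1")
    flags = []
    zero_ref = ref <= 0
    if zero_ref.any():
        flags.append("zero_reference_frequency:" + ",".join(np.array(aas)[zero_ref]))
    fq = counts / total
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = np.where(zero_ref, np.nan, (fq - ref) / np.where(zero_ref, 1.0, ref))
    rng = np.random.default_rng(seed)
    boot = rng.multinomial(int(total), fq, size=n_boot) / total  # (n_boot, n_aa)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_enrich = (boot - ref) / np.where(zero_ref, np.nan, ref)
    alpha = (1.0 - ci) / 2.0
    lo = np.nanpercentile(boot_enrich, 100 * alpha, axis=0)
    hi = np.nanpercentile(boot_enrich, 100 * (1 - alpha), axis=0)
    table = pd.DataFrame(
        {
            "enrichment": enrich,
            "ci_low": np.minimum(lo, enrich),
            "ci_high": np.maximum(hi, enrich),
            "f_query": fq,
            "f_ref": ref,
        },
        index=pd.Index(aas, name="aa"),
    )
    return CompositionProfile(table, n_boot, flags)


def idr_residue_counts(
    ens: EnsembleRecord, idrs: Iterable[IDRAnnotation]
) -> dict[str, int]:
    """Amino-acid counts of all IDR residues of an ensemble (per conformer,
    so a position disordered in k conformers contributes k counts)."""
    counts: dict[str, int] = {}
    by_id = {c.conformer_id: c for c in ens.conformers}
    for ann in idrs:
        conf = by_id[ann.conformer_id]
        for pos in sorted(ann.positions()):
            res = conf.residue_at(pos)
            if res is None:
                continue
            counts[res.aa] = counts.get(res.aa, 0) + 1
    return counts


def load_reference_frequencies(path: str | Path) -> dict[str, float]:
    """Read a two-column delimited table (aa, frequency)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                     names=["aa", "frequency"])
    freqs = {str(r.aa).strip().upper(): float(r.frequency) for r in df.itertuples()}
    total = sum(freqs.values())
    if not np.isclose(total, 1.0, atol=1e-3):
        raise ValueError(f"frequencies in {path} sum to {total:.4f}")
    return freqs
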