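"""Inter-system agreement: event matching, detection performance,
RMSE and ICC(3,1).

Candidate events are matched one-to-one to reference events within the
same (kind, side) stratum by greedy nearest-neighbor pairing under a
250 ms tolerance — a detected event counts as a true positive only if a
reference event of the same type lies within that window. Greedy
pairing equals the optimal assignment whenever timing jitter is small
relative to the inter-event spacing, and is simple to audit.

Detection performance: recall = TP/(TP+FN), precision = TP/(TP+FP),
F1 = harmonic mean of the two. Signed temporal error is defined as
t_reference - t_candidate, so positive means the candidate fired early.

Parameter agreement between two systems over subjects uses the absolute
RMSE, the relative RMSE (normalized by the reference mean), and the
single-measure consistency ICC from the two-way mixed model, ICC(3,1):
(MS_rows - MS_err) / (MS_rows + (k-1) MS_err) with k = 2 raters, which
ignores fixed offsets between the systems (relative agreement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import GaitEvent

log = logging.getLogger(__name__)


@dataclass
class MatchResult:
    """One-to-one event pairing within tolerance, per (kind, side)."""

    pairs: list[tuple[GaitEvent, GaitEvent, float]]
    unmatched_candidate: list[GaitEvent]
    unmatched_reference: list[GaitEvent]
    tolerance: float = 0.250

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_candidate)

    @property
    def fn(self) -> int:
        return len(self.unmatched_reference)

    @property
    def signed_errors(self) -> np.ndarray:
        """t_reference - t_candidate for every matched pair (s)."""
        return np.array([dt for _, _, dt in self.pairs])


@dataclass
class DetectionPerformance:
    tp: int
    fn: int
    fp: int
    recall: float
    precision: float
    f1: float
    mean_abs_time_error: float
    signed_errors: np.ndarray = field(default_factory=lambda: np.array([]))

    def error_histogram(self, bin_width: float = 0.020,
                        limit: float = 0.250) -> tuple[np.ndarray, np.ndarray]:
        """Binned signed Δt (counts, bin edges)."""
        edges = np.arange(-limit, limit + bin_width / 2, bin_width)
        counts, edges = np.histogram(self.signed_errors, bins=edges)
        return counts, edges


@dataclass
class AgreementStats:
    rmse_abs: float
    rmse_rel: float
    icc31: float
    n_subjects: int


def match_events(
    candidate: list[GaitEvent],
    reference: list[GaitEvent],
    tolerance: float = 0.250,
) -> MatchResult:
    """Greedy nearest-neighbor one-to-one matching within tolerance.

    Pairing is restricted to events of the same kind and side; candidate
    pairs are consumed in order of increasing |Δt| (ties broken toward
    the earlier reference event). Leftover candidates are false
    positives, leftover references false negatives.
    """
    pairs: list[tuple[GaitEvent, GaitEvent, float]] = []
    un_c: list[GaitEvent] = []
    un_r: list[GaitEvent] = []
    strata = {(e.kind, e.side) for e in candidate} | {
        (e.kind, e.side) for e in reference
    }
    for kind, side in sorted(strata):
        cs = sorted((e for e in candidate if (e.kind, e.side) == (kind, side)),
                    key=lambda e: e.time)
        rs = sorted((e for e in reference if (e.kind, e.side) == (kind, side)),
                    key=lambda e: e.time)
        options = [
            (abs(r.time - c.time), r.time, ri, ci)
            for ci, c in enumerate(cs)
            for ri, r in enumerate(rs)
            if abs(r.time - c.time) < tolerance
        ]
        options.sort()
        used_c: set[int] = set()
        used_r: set[int] = set()
        for _, _, ri, ci in options:
            if ci in used_c or ri in used_r:
                continue
            used_c.add(ci)
            used_r.add(ri)
            pairs.append((cs[ci], rs[ri], rs[ri].time - cs[ci].time))
        un_c.extend(c for i, c in enumerate(cs) if i not in used_c)
        un_r.extend(r for i, r in enumerate(rs) if i not in used_r)
    return MatchResult(pairs, un_c, un_r, tolerance)


def f1_from_counts(tp: int, fn: int, fp: int) -> float:
    """F1 = harmonic mean of recall TP/(TP+FN) and precision TP/(TP+FP)."""
    if tp == 0:
        return 0.0
    recall = tp / (tp + fn)
    precision = tp / (tp + fp)
    return 2.0 * precision * recall / (precision + recall)


def detection_performance(m: MatchResult) -> DetectionPerformance:
    tp, fn, fp = m.tp, m.fn, m.fp
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    f1 = f1_from_counts(tp, fn, fp)
    errs = m.signed_errors
    mae = float(np.mean(np.abs(errs))) if errs.size else float("nan")
    return DetectionPerformance(tp, fn, fp, recall, precision, f1, mae, errs)


def rmse(
    candidate_values: np.ndarray,
    reference_values: np.ndarray,
    relative: bool = True,
) -> tuple[float, float]:
    """(absolute RMSE, relative RMSE in % of the reference mean)."""
    c = np.asarray(candidate_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    if c.shape != r.shape or c.size < 2:
        raise ValueError("need paired series of equal length >= 2")
    abs_ = float(np.sqrt(np.mean((c - r) ** 2)))
    rel = float("nan")
    if relative:
        mr = float(np.mean(r))
        if mr == 0:
            log.warning("reference mean is zero; relative RMSE undefined")
        else:
            rel = 100.0 * abs_ / mr
    return abs_, rel


def icc31(candidate_values: np.ndarray, reference_values: np.ndarray) -> float:
    """Single-measure consistency ICC, two-way mixed model: ICC(3,1).

    Computed from the two-way ANOVA decomposition of the n x 2 table
    (subjects x raters). Returns NaN when the between-subject variance
    is zero (the coefficient is undefined).
    """
    c = np.asarray(candidate_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    if c.shape != r.shape or c.ndim != 1 or c.size < 3:
        raise ValueError("need >= 3 paired subjects")
    x = np.column_stack([c, r])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom <= 0 or ms_rows == 0:
        log.warning("zero between-subject variance; ICC(3,1) undefined")
        return float("nan")
    return float((ms_rows - ms_err) / denom)


def parameter_agreement(
    candidate: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Per-column agreement report between two subjects x parameters
    tables: rmse_abs, rmse_rel [%], icc31."""
    if not candidate.columns.equals(reference.columns):
        raise ValueError("candidate and reference must share columns")
    rows = {}
    for col in candidate.columns:
        c = candidate[col].to_numpy(dtype=float)
        r = reference[col].to_numpy(dtype=float)
        ok = np.isfinite(c) & np.isfinite(r)
        if ok.sum() < 3:
            rows[col] = {"rmse_abs": float("nan"), "rmse_rel": float("nan"),
                         "icc31": float("nan"), "n_subjects": int(ok.sum())}
            continue
        a, rel = rmse(c[ok], r[ok])
        rows[col] = {"rmse_abs": a, "rmse_rel": rel,
                     "icc31": icc31(c[ok], r[ok]), "n_subjects": int(ok.sum())}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "parameter"
    return out
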