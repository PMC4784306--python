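"""Admixture dating from ancestry tract lengths.

Under a single migration pulse ``T`` generations ago contributing a
fraction ``m`` of ancestry A, ancestry along the genetic map is
approximately a two-state Markov jump process: junctions accumulate at
density ``T`` per Morgan and each junction redraws ancestry from
``(m, 1-m)``, so the process leaves A at rate ``r_A = (1-m) T`` per
Morgan and leaves the complement at ``r_B = m T``.  Chromosome ends and
unassigned call gaps censor the flanking tracts, which then contribute
only survival terms to the likelihood.  Time is converted to years at 30
years per generation.

The three-ancestry (two-pulse) fit uses a marginal approximation: the
youngest pulse is fit on its own tracts against the pooled complement,
and the two older ancestries are fit with the youngest ancestry's tracts
excised, each excision boundary treated as censoring (flanks are *not*
concatenated).
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .tracts import UNASSIGNED, AncestryPath

log = logging.getLogger(__name__)

YEARS_PER_GENERATION = 30.0

_COLS = ["chrom", "segment", "start", "end", "length", "label",
         "left_censored", "right_censored"]


@dataclasses.dataclass
class TractSet:
    """Pooled ancestry tracts with censoring flags.

    ``segment`` identifies a maximal contiguous run of assigned tracts
    (one haplotype chromosome, or a piece of one between call gaps);
    junctions exist only between consecutive tracts of one segment.
    """

    df: pd.DataFrame
    total_length: float

    @property
    def n_tracts(self) -> int:
        return len(self.df)

    def labels(self) -> list[str]:
        return sorted(self.df["label"].unique())

    def lengths(self, label: str, uncensored_only: bool = False) -> np.ndarray:
        d = self.df[self.df["label"] == label]
        if uncensored_only:
            d = d[~(d["left_censored"] | d["right_censored"])]
        return d["length"].to_numpy()

    def data_key(self) -> tuple:
        """Fingerprint used to refuse model comparisons across datasets."""
        return (len(self.df), round(float(self.df["length"].sum()), 9),
                tuple(sorted(self.df["label"].value_counts().items())))


def extract_tracts(paths: AncestryPath | Sequence[AncestryPath],
                   unassigned_label: str = UNASSIGNED) -> TractSet:
    """Pool tract records from one or more haplotype paths.

    The first and last tract of each chromosome are flagged censored;
    unassigned segments are excluded and additionally censor their
    neighbours (gaps split segments, avoiding length inflation).
    """
    if isinstance(paths, AncestryPath):
        paths = [paths]
    rows = []
    seg = 0
    total = 0.0
    for hi, path in enumerate(paths):
        for chrom, tr in path.tracts.items():
            total += tr[-1].end
            runs: list[list] = [[]]
            for t in tr:
                if t.label == unassigned_label:
                    if runs[-1]:
                        runs.append([])
                else:
                    runs[-1].append(t)
            for run in runs:
                if not run:
                    continue
                for i, t in enumerate(run):
                    rows.append((f"{hi}:{chrom}", seg, t.start, t.end, t.length,
                                 t.label,
                                 i == 0,                 # start of segment => censored
                                 i == len(run) - 1))     # end of segment => censored
                seg += 1
    df = pd.DataFrame(rows, columns=_COLS)
    return TractSet(df, total)


# ---------------------------------------------------------------------------
# single-pulse likelihood
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _SuffStats:
    n_start_focal: int
    n_start_other: int
    n_junc_from_focal: int
    n_junc_from_other: int
    len_focal: float
    len_other: float


def _suffstats(tracts: TractSet, focal: str) -> _SuffStats:
    df = tracts.df
    is_f = (df["label"] == focal).to_numpy()
    length = df["length"].to_numpy()
    seg = df["segment"].to_numpy()
    starts = np.concatenate([[True], seg[1:] != seg[:-1]])
    junc_left = ~np.concatenate([seg[1:] != seg[:-1], [True]])  # tract has a right junction
    return _SuffStats(
        int(np.sum(starts & is_f)), int(np.sum(starts & ~is_f)),
        int(np.sum(junc_left & is_f)), int(np.sum(junc_left & ~is_f)),
        float(length[is_f].sum()), float(length[~is_f].sum()),
    )


def _neg_loglik(ss: _SuffStats, T: float, m: float) -> float:
    if not (m > 0.0 and m < 1.0) or not np.isfinite(T) or T <= 0:
        return np.inf
    r_f = (1.0 - m) * T
    r_o = m * T
    ll = ss.n_start_focal * np.log(m) + ss.n_start_other * np.log1p(-m)
    if ss.n_junc_from_focal:
        ll += ss.n_junc_from_focal * np.log(r_f)
    if ss.n_junc_from_other:
        ll += ss.n_junc_from_other * np.log(r_o)
    ll -= r_f * ss.len_focal + r_o * ss.len_other
    return -ll


def single_pulse_loglik(tracts: TractSet, T: float, m: float, ancestry: str) -> float:
    """Negative log-likelihood of the two-state pulse model.

    Per segment: ``log pi`` of the first state (``pi = (m, 1-m)``), plus
    ``log`` of the exit rate at each internal junction, minus
    ``rate(state) * length`` for every tract; censored tracts contribute
    only that survival term.
    """
    if not np.isfinite(T) or not np.isfinite(m):
        raise ValueError("non-finite parameters")
    return _neg_loglik(_suffstats(tracts, ancestry), T, m)


@dataclasses.dataclass
class TractFit:
    model: str
    ancestry: str
    T: int                 # MLE rounded to whole generations
    T_raw: float
    m: float
    neg_loglik: float
    converged: bool
    n_tracts: int
    grid_bounds: tuple = ((1, 50), (0.01, 0.99))
    flat: bool = False
    data_key: tuple | None = None

    @property
    def years(self) -> float:
        return generations_to_years(self.T)

    def n_params(self) -> int:
        return 2


def generations_to_years(generations: float,
                         years_per_generation: float = YEARS_PER_GENERATION) -> float:
    """Convert a generation depth to calendar years (default 30 y/gen)."""
    return generations * years_per_generation


def fit_single_pulse(tracts: TractSet, ancestry: str,
                     t_grid: Sequence[int] = range(1, 51),
                     m_grid: np.ndarray | None = None) -> TractFit:
    """Grid search over (T, m) followed by continuous local refinement."""
    if ancestry not in set(tracts.df["label"]):
        raise KeyError(f"ancestry {ancestry!r} absent from tract set")
    if tracts.n_tracts < 10:
        warnings.warn(f"only {tracts.n_tracts} tracts; the fit will be imprecise",
                      stacklevel=2)
    ss = _suffstats(tracts, ancestry)
    flat = tracts.n_tracts == 1
    if flat:
        log.warning("single censored tract: likelihood is nearly flat in T")
    m_grid = np.arange(0.01, 0.995, 0.01) if m_grid is None else np.asarray(m_grid)
    ts = np.asarray(list(t_grid), dtype=float)
    # vectorized grid evaluation from the sufficient statistics
    Tg, Mg = np.meshgrid(ts, m_grid, indexing="ij")
    r_f = (1.0 - Mg) * Tg
    r_o = Mg * Tg
    with np.errstate(divide="ignore"):
        ll = (ss.n_start_focal * np.log(Mg) + ss.n_start_other * np.log1p(-Mg)
              + ss.n_junc_from_focal * np.where(r_f > 0, np.log(r_f), -np.inf)
              + ss.n_junc_from_other * np.where(r_o > 0, np.log(r_o), -np.inf)
              - r_f * ss.len_focal - r_o * ss.len_other)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    x0 = np.array([ts[i], m_grid[j]])
    res = minimize(lambda x: _neg_loglik(ss, x[0], x[1]), x0,
                   method="L-BFGS-B", bounds=[(1.0, 60.0), (1e-3, 1.0 - 1e-3)])
    if res.fun <= -ll[i, j]:
        T_raw, m_hat, nll, conv = float(res.x[0]), float(res.x[1]), float(res.fun), bool(res.success)
    else:   # refinement failed to improve on the grid optimum
        T_raw, m_hat, nll, conv = float(ts[i]), float(m_grid[j]), float(-ll[i, j]), False
    return TractFit("single_pulse", ancestry, int(round(T_raw)), T_raw, m_hat,
                    nll, conv, tracts.n_tracts,
                    grid_bounds=((int(ts[0]), int(ts[-1])),
                                 (float(m_grid[0]), float(m_grid[-1]))),
                    flat=flat, data_key=tracts.data_key())


# ---------------------------------------------------------------------------
# two-pulse marginal fit
# ---------------------------------------------------------------------------

def _collapse(tracts: TractSet, focal: str, other_label: str = "other") -> TractSet:
    """Relabel every non-focal tract and merge the resulting runs."""
    rows = []
    for seg, d in tracts.df.groupby("segment", sort=False):
        cur = None
        for r in d.itertuples(index=False):
            lab = r.label if r.label == focal else other_label
            if cur is not None and cur[5] == lab:
                cur[3] = r.end
                cur[4] += r.length
                cur[7] = r.right_censored
            else:
                if cur is not None:
                    rows.append(tuple(cur))
                cur = [r.chrom, seg, r.start, r.end, r.length, lab,
                       r.left_censored, r.right_censored]
        if cur is not None:
            rows.append(tuple(cur))
    return TractSet(pd.DataFrame(rows, columns=_COLS), tracts.total_length)


def _excise(tracts: TractSet, remove: str) -> TractSet:
    """Drop one ancestry's tracts, censoring and splitting at each excision."""
    rows = []
    next_seg = 0
    removed_len = 0.0
    for seg, d in tracts.df.groupby("segment", sort=False):
        run: list[list] = []
        for r in d.itertuples(index=False):
            if r.label == remove:
                removed_len += r.length
                if run:
                    run[-1][7] = True          # right flank censored at excision
                    for row in run:
                        rows.append(tuple(row))
                    run = []
                    next_seg += 1
                continue
            run.append([r.chrom, next_seg, r.start, r.end, r.length, r.label,
                        r.left_censored, r.right_censored])
        for row in run:
            rows.append(tuple(row))
        next_seg += 1
    out = pd.DataFrame(rows, columns=_COLS)
    # a tract that opens a new segment is left-censored by construction
    seg_col = out["segment"].to_numpy()
    starts = np.concatenate([[True], seg_col[1:] != seg_col[:-1]]) if len(out) else []
    out["left_censored"] = np.asarray(starts, dtype=bool) | out["left_censored"].to_numpy()
    return TractSet(out, tracts.total_length - removed_len)


def fit_two_pulse_marginal(tracts: TractSet, pulse_order: Sequence[str],
                           ) -> tuple[list[TractFit], float]:
    """Marginal two-pulse fit for a three-ancestry history.

    ``pulse_order = (founding, older_pulse, youngest_pulse)``.  Returns
    ``([older_fit, youngest_fit], combined_neg_loglik)``.  The older fit
    estimates the founding ancestry's fraction against the older pulse
    ancestry on the genome with the youngest ancestry excised.  If the
    youngest ancestry has no tracts the fit degenerates exactly to the
    single-pulse fit on the remaining two (its pulse fraction -> 0).
    """
    if len(pulse_order) != 3:
        raise ValueError("pulse_order must name (founding, older, youngest)")
    founding, older, youngest = pulse_order
    present = set(tracts.df["label"])
    for lab in (founding, older):
        if lab not in present:
            raise KeyError(f"ancestry {lab!r} absent from tract set")
    fits: list[TractFit] = []
    if youngest in present:
        young_fit = fit_single_pulse(_collapse(tracts, youngest), youngest)
        young_fit = dataclasses.replace(young_fit, model="two_pulse_marginal",
                                        data_key=tracts.data_key())
        old_set = _excise(tracts, youngest)
        combined_extra = young_fit.neg_loglik
    else:
        young_fit = None
        old_set = tracts
        combined_extra = 0.0
    old_fit = fit_single_pulse(_collapse(old_set, founding), founding)
    old_fit = dataclasses.replace(old_fit, model="two_pulse_marginal",
                                  ancestry=founding, data_key=tracts.data_key())
    fits.append(old_fit)
    if young_fit is not None:
        fits.append(young_fit)
    return fits, old_fit.neg_loglik + combined_extra


def compare_models(fits: Sequence[TractFit],
                   combined: Sequence[tuple[str, float, int]] = ()) -> pd.DataFrame:
    """Rank fits on one dataset by negative log-likelihood.

    ``combined`` may carry extra (name, neg_loglik, n_params) rows, e.g. a
    summed two-pulse likelihood.  Fits on different data raise.  No
    automatic p-values: the pulse models are not all nested and the grid
    optimum need not be interior.
    """
    if len(fits) + len(combined) < 1:
        raise ValueError("nothing to compare")
    keys = {f.data_key for f in fits if f.data_key is not None}
    if len(keys) > 1:
        raise ValueError("fits were computed on different tract data")
    rows = [(f"{f.model}[{f.ancestry}]", f.neg_loglik, f.n_params(), f.T, f.m)
            for f in fits]
    rows += [(name, nll, k, np.nan, np.nan) for name, nll, k in combined]
    df = pd.DataFrame(rows, columns=["model", "neg_loglik", "n_params", "T", "m"])
    df = df.sort_values(["neg_loglik", "model"], kind="stable").reset_index(drop=True)
    df["delta_neg_loglik"] = df["neg_loglik"] - df["neg_loglik"].iloc[0]
    return df
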