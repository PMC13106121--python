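"""Similarity statistics over normalized activation profiles.

The core statistic is a lag-constrained cross-correlation between two
100-point movement-cycle profiles: the similarity is maximized over integer
shifts of up to ``max_lag`` points (1 point = 1% of cycle; default ±25), so
small physiological timing offsets do not deflate shape similarity.

Two similarity definitions are supported:

* ``"norm_coeff"`` (default) — the normalized cross-correlation
  ``sum_i a[i] b[i+k] / (||a|| ||b||)`` with full-vector Euclidean norms and
  truncated (no-padding) overlap, the usual choice for non-negative envelopes.
* ``"pearson"`` — Pearson correlation of the overlapping segments.

From the pairwise statistic the module builds the study-level descriptors:
intra-subject repeatability (over repetition pairs within subjects),
inter-subject reproducibility (over pairs of subject-mean profiles), a
composite score per muscle (arithmetic mean of the intra and inter means), a
ranking table, and group mean±SD curves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DegenerateInputError, LengthError, ParameterError, SchemaError
from .preprocessing import N_POINTS

DEFAULT_MAX_LAG = 25  # points of the 100-point cycle grid, i.e. ±25% of cycle


@dataclass(frozen=True)
class LagCorrResult:
    """Maximum windowed cross-correlation and the lag achieving it.

    ``best_lag > 0`` means the second profile is delayed relative to the first.
    Ties are broken toward the smallest |lag|, then toward the negative lag.
    """

    coefficient: float
    best_lag: int
    method: str


def _overlap(a: np.ndarray, b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    # segment pairs (a[i], b[i+k]) that exist for shift k
    if k >= 0:
        return a[: a.size - k], b[k:]
    return a[-k:], b[: b.size + k]


def lagged_xcorr(
    a: Sequence[float],
    b: Sequence[float],
    max_lag: int = DEFAULT_MAX_LAG,
    method: str = "norm_coeff",
) -> LagCorrResult:
    """Lag-constrained cross-correlation of two 100-point profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (N_POINTS,) or b.shape != (N_POINTS,):
        raise LengthError(f"profiles must have exactly {N_POINTS} points")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ParameterError("profiles must be finite")
    if max_lag < 0 or max_lag >= N_POINTS:
        raise ParameterError(f"max_lag must be in [0, {N_POINTS - 1}]")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        raise DegenerateInputError("both profiles are constant")
    if method not in ("norm_coeff", "pearson"):
        raise ParameterError(f"unknown method {method!r}")

    if method == "norm_coeff":
        denom = float(np.linalg.norm(a) * np.linalg.norm(b))
        if denom == 0.0:
            raise DegenerateInputError("zero-norm profile under norm_coeff method")

    best: LagCorrResult | None = None
    # visiting lags by (|k|, k) makes "first strict maximum wins" implement the
    # tie-break: smallest |lag| first, negative before positive
    for k in sorted(range(-max_lag, max_lag + 1), key=lambda k: (abs(k), k)):
        sa, sb = _overlap(a, b, k)
        if method == "norm_coeff":
            c = float(np.dot(sa, sb)) / denom
        else:
            if sa.size < 2 or np.ptp(sa) == 0.0 or np.ptp(sb) == 0.0:
                continue
            c = float(np.corrcoef(sa, sb)[0, 1])
        if best is None or c > best.coefficient:
            best = LagCorrResult(c, k, method)
    if best is None:
        raise DegenerateInputError("no lag produced a defined correlation")
    return best


def mean_profile(profiles: Sequence[Sequence[float]]) -> np.ndarray:
    """Pointwise arithmetic mean of repetition profiles (the subject-level profile)."""
    arr = np.asarray(profiles, dtype=float)
    if arr.size == 0:
        raise DegenerateInputError("no profiles to average")
    arr = np.atleast_2d(arr)
    if arr.shape[1] != N_POINTS:
        raise LengthError(f"profiles must have {N_POINTS} points")
    return arr.mean(axis=0)


@dataclass(frozen=True)
class IntraResult:
    """Intra-subject repeatability for one muscle.

    ``mean``/``sd`` aggregate per-subject means across subjects (SD with n-1);
    ``per_subject`` holds each subject's mean over repetition pairs and
    ``pair_values`` every pairwise coefficient keyed (subject, rep_i, rep_j).
    """

    mean: float
    sd: float
    per_subject: pd.Series
    pair_values: pd.Series


@dataclass(frozen=True)
class InterResult:
    """Inter-subject reproducibility for one muscle: stats over all subject pairs."""

    mean: float
    sd: float
    pairwise: pd.DataFrame


def intra_subject(
    profiles_by_subject: Mapping[Any, np.ndarray],
    max_lag: int = DEFAULT_MAX_LAG,
    method: str = "norm_coeff",
    aggregate: str = "subjects",
) -> IntraResult:
    """Repeatability of one muscle across repetitions.

    ``profiles_by_subject`` maps subject -> array (n_reps, 100). Per subject the
    lag-constrained coefficient is computed for every unordered repetition pair
    and averaged; with ``aggregate="subjects"`` (default) the reported mean and
    SD (n-1) are taken across the per-subject means, keeping subjects equally
    weighted; ``aggregate="pairs"`` pools all pairwise values instead.
    """
    if aggregate not in ("subjects", "pairs"):
        raise ParameterError(f"unknown aggregate {aggregate!r}")
    per_subject = {}
    pair_index, pair_vals = [], []
    for subject, reps in profiles_by_subject.items():
        arr = np.atleast_2d(np.asarray(reps, dtype=float))
        if arr.shape[0] < 2:
            raise DegenerateInputError(f"subject {subject!r} has fewer than 2 repetitions")
        vals = []
        for i, j in itertools.combinations(range(arr.shape[0]), 2):
            c = lagged_xcorr(arr[i], arr[j], max_lag, method).coefficient
            vals.append(c)
            pair_index.append((subject, i + 1, j + 1))
            pair_vals.append(c)
        per_subject[subject] = float(np.mean(vals))
    per_subject = pd.Series(per_subject, name="intra_mean")
    pairs = pd.Series(
        pair_vals,
        index=pd.MultiIndex.from_tuples(pair_index, names=["subject_id", "rep_i", "rep_j"]),
        name="coefficient",
    )
    pooled = pairs.to_numpy() if aggregate == "pairs" else per_subject.to_numpy()
    return IntraResult(
        mean=float(np.mean(pooled)),
        sd=float(np.std(pooled, ddof=1)) if pooled.size > 1 else float("nan"),
        per_subject=per_subject,
        pair_values=pairs,
    )


def inter_subject(
    mean_profiles: Mapping[Any, np.ndarray],
    max_lag: int = DEFAULT_MAX_LAG,
    method: str = "norm_coeff",
) -> InterResult:
    """Reproducibility of one muscle across subjects' mean profiles.

    Mean and SD (n-1) are taken over all unordered subject pairs; the returned
    pairwise matrix is symmetric with unit diagonal.
    """
    subjects = list(mean_profiles)
    if len(subjects) < 2:
        raise DegenerateInputError("inter-subject analysis needs at least 2 subjects")
    mat = pd.DataFrame(np.eye(len(subjects)), index=subjects, columns=subjects)
    vals = []
    for i, j in itertools.combinations(range(len(subjects)), 2):
        c = lagged_xcorr(
            mean_profiles[subjects[i]], mean_profiles[subjects[j]], max_lag, method
        ).coefficient
        mat.iat[i, j] = mat.iat[j, i] = c
        vals.append(c)
    vals = np.asarray(vals)
    return InterResult(
        mean=float(vals.mean()),
        sd=float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
        pairwise=mat,
    )


def composite_score(intra_mean: float, inter_mean: float) -> float:
    """Composite reproducibility score: arithmetic mean of the intra and inter means."""
    for v in (intra_mean, inter_mean):
        if not np.isfinite(v) or not -1.0 <= v <= 1.0:
            raise ParameterError(f"correlation {v} outside [-1, 1]")
    return (intra_mean + inter_mean) / 2.0


def _mean_sd(entry) -> tuple[float, float]:
    if hasattr(entry, "mean") and hasattr(entry, "sd"):
        return float(entry.mean), float(entry.sd)
    m, s = entry
    return float(m), float(s)


def build_table(
    intra: Mapping[str, Any],
    inter: Mapping[str, Any],
) -> pd.DataFrame:
    """Per-muscle summary table with composite score and rank.

    ``intra`` and ``inter`` map muscle -> result object (or (mean, sd) pair)
    over the same muscle set. Ranks are 1-based by descending composite; ties
    break by descending intra mean, then by input muscle order. Values are kept
    at full precision — rounding happens only at report time.
    """
    muscles = list(intra)
    if set(muscles) != set(inter):
        raise SchemaError(
            f"muscle sets differ: {sorted(intra)} vs {sorted(inter)}"
        )
    rows = []
    for m in muscles:
        im, isd = _mean_sd(intra[m])
        em, esd = _mean_sd(inter[m])
        rows.append(
            {
                "muscle": m,
                "intra_mean": im,
                "intra_sd": isd,
                "inter_mean": em,
                "inter_sd": esd,
                "composite": composite_score(im, em),
            }
        )
    table = pd.DataFrame(rows).set_index("muscle")
    order = sorted(
        range(len(muscles)),
        key=lambda i: (-table["composite"].iloc[i], -table["intra_mean"].iloc[i], i),
    )
    ranks = np.empty(len(muscles), dtype=int)
    ranks[order] = np.arange(1, len(muscles) + 1)
    table["rank"] = ranks
    return table


def group_profiles(mean_profiles: Mapping[Any, np.ndarray]) -> pd.DataFrame:
    """Group mean and SD curves across subjects for one muscle.

    Returns a table (point_index, mean, sd) with pointwise mean and SD (n-1)
    over the subjects' mean profiles.
    """
    arr = np.vstack([np.asarray(v, dtype=float) for v in mean_profiles.values()])
    if arr.shape[0] < 2:
        raise DegenerateInputError("group curves need at least 2 subjects")
    if arr.shape[1] != N_POINTS:
        raise LengthError(f"profiles must have {N_POINTS} points")
    return pd.DataFrame(
        {
            "point_index": np.arange(N_POINTS),
            "mean": arr.mean(axis=0),
            "sd": arr.std(axis=0, ddof=1),
        }
    )


# ---------------------------------------------------------------------------
# Estimator over the long-format profile table
# ---------------------------------------------------------------------------

_PROFILE_COLS = {"subject_id", "muscle", "rep_index", "point_index", "value"}


def profiles_to_arrays(profiles: pd.DataFrame) -> dict[str, dict[Any, np.ndarray]]:
    """Pivot the long profile table into muscle -> subject -> (n_reps, 100) arrays."""
    if not _PROFILE_COLS.issubset(profiles.columns):
        raise SchemaError(f"profile table must have columns {sorted(_PROFILE_COLS)}")
    out: dict[str, dict[Any, np.ndarray]] = {}
    for (muscle, subject), grp in profiles.groupby(["muscle", "subject_id"], sort=False):
        reps = []
        for rep, rep_grp in grp.sort_values(["rep_index", "point_index"]).groupby(
            "rep_index", sort=True
        ):
            vals = rep_grp["value"].to_numpy()
            if vals.size != N_POINTS:
                raise SchemaError(
                    f"subject {subject} muscle {muscle} rep {rep}: "
                    f"{vals.size} points instead of {N_POINTS}"
                )
            reps.append(vals)
        out.setdefault(muscle, {})[subject] = np.vstack(reps)
    return out


class ReproducibilityAnalysis(BaseEstimator):
    """Estimator computing repeatability/reproducibility descriptors per muscle.

    ``fit`` consumes the long-format profile table produced by the
    preprocessing stage and exposes:

    ``table_``
        per-muscle intra mean±SD, inter mean±SD, composite score and rank;
    ``intra_``, ``inter_``
        the per-muscle :class:`IntraResult` / :class:`InterResult` details;
    ``subject_means_``
        muscle -> subject -> 100-point subject-mean profile;
    ``group_profiles_``
        long table (muscle, point_index, mean, sd) of group curves.
    """

    def __init__(
        self,
        max_lag: int = DEFAULT_MAX_LAG,
        method: str = "norm_coeff",
        aggregate: str = "subjects",
    ):
        self.max_lag = max_lag
        self.method = method
        self.aggregate = aggregate

    def fit(self, X: pd.DataFrame, y=None) -> "ReproducibilityAnalysis":
        by_muscle = profiles_to_arrays(X)
        self.intra_ = {}
        self.inter_ = {}
        self.subject_means_ = {}
        group_rows = []
        for muscle, per_subject in by_muscle.items():
            self.intra_[muscle] = intra_subject(
                per_subject, self.max_lag, self.method, self.aggregate
            )
            means = {s: mean_profile(reps) for s, reps in per_subject.items()}
            self.subject_means_[muscle] = means
            self.inter_[muscle] = inter_subject(means, self.max_lag, self.method)
            gp = group_profiles(means)
            gp.insert(0, "muscle", muscle)
            group_rows.append(gp)
        self.table_ = build_table(self.intra_, self.inter_)
        self.group_profiles_ = pd.concat(group_rows, ignore_index=True)
        return self
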