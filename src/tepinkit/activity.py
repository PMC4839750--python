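"""Active-time-point detection from expression time courses.

The core rule is the *deviation degree* threshold: a gene is active at time
point t exactly when its expression there strictly exceeds its own
time-course mean plus one sample standard deviation.  Using each gene's own
moments (rather than one global cutoff) keeps constitutively low- or
high-expressed genes from being filtered out wholesale: a flat profile is
never active, while any profile with genuine excursions is active exactly
where it peaks.

Detectors follow the scikit-learn estimator protocol (``fit`` /
``transform`` / ``get_params``) and operate on a (n_genes, n_timepoints)
array or an :class:`~tepinkit.datatypes.ExpressionMatrix`.  Any callable
mapping an expression row to a set of 1-based active time points can be
plugged into the downstream builders instead.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .datatypes import ActivityProfile, ActivitySchedule, ExpressionMatrix


def _as_array(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("expected a (n_genes, n_timepoints) array")
    if not np.all(np.isfinite(X)):
        raise ValueError("expression values must be finite")
    return X


class BaseActivityDetector:
    """Minimal scikit-learn-compatible base: per-row thresholds fitted from
    the data, activity = strict exceedance of the threshold."""

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in self.__init__.__code__.co_varnames[1:self.__init__.__code__.co_argcount]  # noqa: E501
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        """Boolean (n_genes, n_timepoints) activity matrix for the rows of X,
        thresholded row-wise with this detector's fitted thresholds."""
        X = _as_array(X)
        if not hasattr(self, "threshold_"):
            raise RuntimeError("detector is not fitted")
        return X > np.asarray(self.threshold_)[:, None]

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def __call__(self, row: np.ndarray) -> frozenset[int]:
        """Detector-function form: one row -> 1-based active time points."""
        active = type(self)(**self.get_params()).fit_transform(row)[0]
        return frozenset(int(t) for t in np.flatnonzero(active) + 1)


class DeviationDegreeDetector(BaseActivityDetector):
    """Active iff expression strictly exceeds mean + 1 sample SD of the row.

    The sample standard deviation uses the n-1 denominator, so rows need at
    least two time points.  A constant row has SD 0 and is never active
    (nothing is strictly above its own mean).

    Fitted attributes: ``mean_``, ``sd_``, ``threshold_`` (all per-row).
    """

    def __init__(self) -> None:
        pass

    def fit(self, X, y=None) -> "DeviationDegreeDetector":
        X = _as_array(X)
        if X.shape[1] < 2:
            raise ValueError("deviation degree needs >= 2 time points")
        self.mean_ = X.mean(axis=1)
        self.sd_ = X.std(axis=1, ddof=1)
        self.threshold_ = self.mean_ + self.sd_
        return self


class GlobalThresholdDetector(BaseActivityDetector):
    """Baseline: active iff expression strictly exceeds a fixed global cutoff
    ``c`` (with c = -inf every gene is active everywhere)."""

    def __init__(self, c: float = 0.0) -> None:
        self.c = c

    def fit(self, X, y=None) -> "GlobalThresholdDetector":
        X = _as_array(X)
        self.mean_ = X.mean(axis=1)
        self.sd_ = X.std(axis=1, ddof=1) if X.shape[1] > 1 else np.zeros(len(X))
        self.threshold_ = np.full(X.shape[0], float(self.c))
        return self


def deviation_degree_profile(expr_row: np.ndarray, gene: str = "") -> ActivityProfile:
    """Deviation-degree activity profile of a single expression row."""
    det = DeviationDegreeDetector().fit(expr_row)
    active = det.transform(expr_row)[0]
    return ActivityProfile(
        gene=gene,
        mean=float(det.mean_[0]),
        sd=float(det.sd_[0]),
        threshold=float(det.threshold_[0]),
        active_timepoints=frozenset(int(t) for t in np.flatnonzero(active) + 1),
    )


def active_sets(
    expr: ExpressionMatrix, detector: BaseActivityDetector | None = None
) -> ActivitySchedule:
    """Fit a detector to every gene and collect the schedule of per-time-point
    active protein sets {ActiveProteins_T1, ..., ActiveProteins_Tn}."""
    det = detector if detector is not None else DeviationDegreeDetector()
    active = det.fit_transform(expr)
    have_moments = hasattr(det, "mean_")
    profiles: dict[str, ActivityProfile] = {}
    for i, gene in enumerate(expr.genes):
        profiles[gene] = ActivityProfile(
            gene=gene,
            mean=float(det.mean_[i]) if have_moments else float("nan"),
            sd=float(det.sd_[i]) if have_moments else float("nan"),
            threshold=float(det.threshold_[i]),
            active_timepoints=frozenset(
                int(t) for t in np.flatnonzero(active[i]) + 1
            ),
        )
    return ActivitySchedule(profiles, expr.n_timepoints)


def activity_histogram(schedule: ActivitySchedule) -> dict[int, int]:
    """Distribution of the number of active time points per protein: maps
    count-of-active-time-points -> number of proteins.  Totals always equal
    the number of genes in the schedule."""
    counts = Counter(len(p.active_timepoints) for p in schedule.profiles.values())
    return dict(sorted(counts.items()))
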