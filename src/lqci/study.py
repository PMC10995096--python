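"""The packaged case study: the 8-year, 17-input training protocol.

Convenience layer binding the packaged tables to the estimators: load the
yearly samples (inputs from the socio-economic/ecological table, targets
from the truth composite-index series), train plain-BP and GA-BP models
under the study defaults, and run the leave-one-out validation.  Both the
test suite and the reproduction script drive the pipeline through these
functions so the protocol is defined in exactly one place.
"""

from __future__ import annotations

import numpy as np

from .evaluation import CVResult, MetricsReport, compute_metrics, loocv
from .fixtures import load_fixture, table3_matrix
from .genetic import GABPRegressor
from .network import BPRegressor

__all__ = [
    "load_study_samples",
    "train_study_model",
    "study_metrics_over_seeds",
    "study_loocv",
]


def load_study_samples() -> tuple[np.ndarray, np.ndarray, list[int]]:
    """(X, y, years): the 8x17 raw input matrix and truth LQCI targets."""
    years, _, X_df = table3_matrix()
    truth = {r.year: r.truth_lqci for r in load_fixture("table6")}
    y = np.array([truth[yr] for yr in years], dtype=float)
    return X_df.to_numpy(dtype=float), y, years


def train_study_model(model: str, master_seed: int, **overrides):
    """Train one model ('bp' or 'gabp') on the full 8-year sample with the
    study defaults; returns the fitted estimator."""
    X, y, _ = load_study_samples()
    cls = {"bp": BPRegressor, "gabp": GABPRegressor}[model]
    est = cls(random_state=master_seed, **overrides)
    est.fit(X, y)
    return est


def study_metrics_over_seeds(model: str, seeds, **overrides
                             ) -> list[MetricsReport]:
    """Training-set metrics (denormalized LQCI scale) for each seed."""
    X, y, _ = load_study_samples()
    cls = {"bp": BPRegressor, "gabp": GABPRegressor}[model]
    out = []
    for s in seeds:
        est = cls(random_state=int(s), **overrides).fit(X, y)
        out.append(compute_metrics(y, est.predict(X)))
    return out


def study_loocv(master_seed: int, model: str = "gabp", **overrides) -> CVResult:
    """Leave-one-out over the 8 years with fold-local normalization."""
    X, y, _ = load_study_samples()
    cls = {"bp": BPRegressor, "gabp": GABPRegressor}[model]
    return loocv(X, y, cls(**overrides), master_seed=master_seed)
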