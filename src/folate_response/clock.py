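"""Filtered multi-tissue epigenetic clock: training, prediction, age deltas.

The clock is a penalized linear regression of transformed chronological age
on methylation beta values at a fixed whitelist of CpG sites, in the style
of the multi-tissue clock restricted to the CpGs shared across array
platforms ("filtered" model). Chronological age is mapped through the
piecewise log/linear transform

    F(age) = log((age + 1) / (adult_age + 1))        for age <= adult_age
    F(age) = (age - adult_age) / (adult_age + 1)     otherwise

with ``adult_age`` = 20 by default; predictions are mapped back through the
exact inverse. Coefficients are fit by elastic net, with the penalty
strength chosen by internal cross-validation unless fixed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from . import stratification as strat

DEFAULT_ADULT_AGE = 20.0


def age_transform(age, adult_age: float = DEFAULT_ADULT_AGE):
    """Piecewise log/linear transform of chronological age (years)."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("ages must be non-negative")
    if adult_age <= 0:
        raise ValueError("adult_age must be positive")
    out = np.where(
        age <= adult_age,
        np.log((age + 1.0) / (adult_age + 1.0)),
        (age - adult_age) / (adult_age + 1.0),
    )
    return float(out) if out.ndim == 0 else out


def inverse_age_transform(t, adult_age: float = DEFAULT_ADULT_AGE):
    """Exact inverse of :func:`age_transform`, returning years."""
    t = np.asarray(t, dtype=float)
    out = np.where(
        t <= 0,
        np.exp(t) * (adult_age + 1.0) - 1.0,
        t * (adult_age + 1.0) + adult_age,
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class ClockModel:
    """A trained clock: CpG whitelist, intercept and per-CpG weights.

    ``coefficients`` is aligned with ``whitelist`` and expressed in
    transformed-age units per beta unit.
    """

    whitelist: list[str]
    intercept: float
    coefficients: np.ndarray
    adult_age: float = DEFAULT_ADULT_AGE

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.whitelist):
            raise ValueError("coefficients must align with the whitelist")
        if self.adult_age <= 0:
            raise ValueError("adult_age must be positive")

    @property
    def nonzero_count(self) -> int:
        return int(np.count_nonzero(self.coefficients))


def _whitelist_matrix(beta: pd.DataFrame, whitelist: list[str]) -> np.ndarray:
    missing = [c for c in whitelist if c not in beta.index]
    if missing:
        head = ", ".join(missing[:5])
        raise KeyError(
            f"{len(missing)} whitelist CpG(s) missing from the beta matrix: {head}"
        )
    # samples x CpGs
    return beta.loc[list(whitelist)].to_numpy(dtype=float).T


def train_filtered_clock(
    beta: pd.DataFrame,
    ages,
    whitelist: list[str],
    l1_ratio: float = 0.5,
    alpha: float | None = None,
    cv: int = 10,
    seed: int = 0,
) -> ClockModel:
    """Fit the whitelist-restricted elastic-net clock.

    Parameters
    ----------
    beta : CpG-by-sample matrix (rows CpG ids, columns sample ids).
    ages : chronological ages (years), one per sample column.
    whitelist : ordered CpG ids the model may use; all must be present.
    l1_ratio : elastic-net mixing parameter (1 = lasso, 0 = ridge).
    alpha : fixed penalty strength; when None it is chosen by ``cv``-fold
        cross-validation with a seeded fold split.
    """
    ages = np.asarray(ages, dtype=float)
    if beta.shape[1] != len(ages):
        raise ValueError("one age per sample column is required")
    if len(ages) < 10:
        raise ValueError("need at least 10 training samples")
    if np.ptp(ages) == 0:
        raise ValueError("training ages are constant; the clock is unidentifiable")
    X = _whitelist_matrix(beta, whitelist)
    y = age_transform(ages)
    if alpha is not None:
        est = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=20000, tol=1e-7)
        est.fit(X, y)
    else:
        folds = KFold(n_splits=min(cv, len(ages)), shuffle=True, random_state=seed)
        # CV over a descending alpha ladder; if the minimum wins, the data
        # want less regularization (e.g. near-noiseless input), so extend
        # the grid downward and refit until the optimum is interior.
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        alpha_max = np.max(np.abs(Xc.T @ yc)) / (len(y) * max(l1_ratio, 0.01))
        grid = np.geomspace(alpha_max, alpha_max * 1e-3, 30)
        for _ in range(5):
            est = ElasticNetCV(
                l1_ratio=l1_ratio, alphas=grid, cv=folds,
                max_iter=10000, tol=1e-5, n_jobs=1,
            )
            est.fit(X, y)
            if est.alpha_ > grid.min() * 1.0001 or grid.min() < 1e-12:
                break
            grid = np.geomspace(est.alpha_, est.alpha_ * 1e-3, 20)
    return ClockModel(
        whitelist=list(whitelist),
        intercept=float(est.intercept_),
        coefficients=np.asarray(est.coef_, dtype=float),
    )


def predict_age(model: ClockModel, beta, impute_mean: bool = False):
    """Predict biological age (years) for one sample or a matrix of samples.

    ``beta`` may be a Series (index CpG ids) or a CpG-by-sample DataFrame.
    CpGs outside the whitelist are ignored. A missing whitelist CpG raises
    unless ``impute_mean`` is set, in which case it is filled with the mean
    beta of the present whitelist CpGs in that sample.
    """
    single = isinstance(beta, pd.Series)
    frame = beta.to_frame() if single else beta
    missing = [c for c in model.whitelist if c not in frame.index]
    if missing and not impute_mean:
        head = ", ".join(missing[:5])
        raise KeyError(f"missing whitelist CpG(s): {head}")
    frame = frame.copy()
    if missing:
        present = [c for c in model.whitelist if c in frame.index]
        fill = frame.loc[present].mean(axis=0)
        for cpg in missing:
            frame.loc[cpg] = fill
    X = _whitelist_matrix(frame, model.whitelist)
    t = model.intercept + X @ model.coefficients
    years = inverse_age_transform(t, model.adult_age)
    if single:
        return float(years[0])
    return pd.Series(years, index=frame.columns, name="predicted_age")


@dataclass(frozen=True)
class AgeDelta:
    """Per-patient biological-age change (years), post minus baseline."""

    patient_id: str
    bioage_before: float
    bioage_after: float

    @property
    def delta(self) -> float:
        return self.bioage_after - self.bioage_before


def cohort_age_deltas(
    model: ClockModel,
    beta_before: pd.DataFrame,
    beta_after: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> tuple[list[AgeDelta], pd.DataFrame]:
    """Predict both timepoints and summarize the deltas per response group.

    The two matrices must share identical sample columns. Returns the
    per-patient deltas plus a group-summary frame: n, mean/sd delta,
    fraction of patients with strictly decreasing biological age, and the
    gated paired test on the predictions.
    """
    if list(beta_before.columns) != list(beta_after.columns):
        raise ValueError("before/after beta matrices must have matching sample columns")
    pred_b = predict_age(model, beta_before)
    pred_a = predict_age(model, beta_after)
    deltas = [
        AgeDelta(pid, float(pred_b[pid]), float(pred_a[pid]))
        for pid in beta_before.columns
    ]
    frame = pd.DataFrame(
        {
            "patient_id": [d.patient_id for d in deltas],
            "delta": [d.delta for d in deltas],
        }
    )
    if labels is not None:
        frame = frame.merge(labels[["patient_id", "label"]], on="patient_id", how="left")
    else:
        frame["label"] = "all"
    rows = []
    groups = [("all", frame)] + (
        [(g, frame[frame["label"] == g]) for g in (strat.RESPONDER, strat.NON_RESPONDER)]
        if labels is not None
        else []
    )
    for name, sub in groups:
        if sub.empty:
            continue
        mean, sd, n = strat.summarize_group(sub["delta"])
        ids = list(sub["patient_id"])
        test = (
            strat.paired_compare(pred_b[ids], pred_a[ids], alpha=alpha)
            if n >= 3
            else None
        )
        rows.append(
            {
                "group": name,
                "n": n,
                "mean_delta_years": mean,
                "sd_delta_years": sd,
                "fraction_decreasing": float(np.mean(sub["delta"] < 0)),
                "test_used": test.test_used if test else "",
                "p_value": test.p_value if test else float("nan"),
            }
        )
    return deltas, pd.DataFrame(rows)


def write_model(model: ClockModel, path) -> None:
    """Serialize a clock to a flat TSV; round-trips bit-exactly."""
    with open(path, "w") as fh:
        fh.write(f"#intercept\t{model.intercept!r}\n")
        fh.write(f"#adult_age\t{model.adult_age!r}\n")
        fh.write("cpg_id\tcoefficient\n")
        for cpg, w in zip(model.whitelist, model.coefficients):
            fh.write(f"{cpg}\t{float(w)!r}\n")


def read_model(path) -> ClockModel:
    """Load a clock serialized by :func:`write_model`."""
    intercept = adult_age = None
    cpgs: list[str] = []
    coefs: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, _, value = line.partition("\t")
            if key == "#intercept":
                intercept = float(value)
            elif key == "#adult_age":
                adult_age = float(value)
            elif key == "cpg_id":
                continue
            else:
                cpgs.append(key)
                coefs.append(float(value))
    if intercept is None or adult_age is None:
        raise ValueError("model file is missing its intercept/adult_age header")
    return ClockModel(cpgs, intercept, np.array(coefs), adult_age)
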