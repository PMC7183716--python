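"""Cost-prediction model zoo: Gamma GLM, PLAQR and random forest.

Three estimators behind one fit/predict contract, each available as a
correctly specified variant (B-spline terms for the nonlinear covariates
plus the x3*x5 interaction) and a misspecified main-effects-only variant.
The specification flag only changes the design matrix of the two regression
models; the random forest always receives the ten raw covariates and detects
structure itself.

Follows the statsmodels idiom: a model object is constructed from data and a
:class:`ModelSpec`, ``fit()`` returns a :class:`CostModelResults` carrying
the estimates, convergence status, diagnostics and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.random import SeedSequence
from patsy import build_design_matrices, dmatrix
from sklearn.ensemble import RandomForestRegressor

from .simulate import COVARIATE_COLUMNS, SimulatedDataset

__all__ = [
    "ModelSpec",
    "CostModelResults",
    "GammaGLM",
    "PLAQR",
    "RandomForestCost",
    "build_design",
    "fit_model",
    "fit_gamma_glm",
    "fit_plaqr",
    "fit_rf",
    "predict",
]

MODEL_FAMILIES = ("gamma_glm", "plaqr", "rf")
SPECIFICATIONS = ("correct", "main_effects")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one estimator variant.

    Parameters
    ----------
    family : {"gamma_glm", "plaqr", "rf"}
    specification : {"correct", "main_effects"}
        "correct" builds cubic B-splines (``spline_df`` columns each) for
        z1, z2, x8 and adds the x3*x5 interaction; "main_effects" keeps all
        ten covariates linear.  Ignored by the random forest.
    tau : float
        Quantile level for PLAQR (median regression by default).
    rf_mtry : int or None
        Candidate predictors per split.  ``None`` selects the value in
        ``rf_mtry_grid`` minimising out-of-bag MSE (ties toward smaller
        values), using ``rf_tune_ntree`` trees per candidate.
    rf_min_leaf : int
        Minimum terminal-node size; 5 is the classical regression-forest
        default.  Tree depth is unlimited (full-grown trees).
    """

    family: str
    specification: str = "correct"
    tau: float = 0.5
    spline_df: int = 3
    rf_ntree: int = 1000
    rf_mtry: int | None = None
    rf_mtry_grid: tuple[int, ...] = tuple(range(1, 11))
    rf_tune_ntree: int = 100
    rf_min_leaf: int = 5
    glm_maxiter: int = 100
    glm_tol: float = 1e-8
    qr_max_iter: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.specification not in SPECIFICATIONS:
            raise ValueError(f"unknown specification {self.specification!r}")
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie strictly between 0 and 1")
        if self.rf_ntree < 1:
            raise ValueError("rf_ntree must be at least 1")

    @property
    def label(self) -> str:
        return f"{self.family}/{self.specification}"


def _formula(spec: ModelSpec) -> str:
    linear = "x1 + x2 + x3 + x4 + x5 + x6 + C(x7)"
    if spec.specification == "correct":
        df = spec.spline_df
        return (
            f"{linear} + bs(z1, df={df}) + bs(z2, df={df}) + bs(x8, df={df}) + x3:x5"
        )
    return f"{linear} + z1 + z2 + x8"


def _check_schema(cov: pd.DataFrame) -> None:
    missing = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing:
        raise KeyError(f"covariate table is missing columns: {missing}")


_NONLINEAR = ("z1", "z2", "x8")


def _spline_clipper(cov: pd.DataFrame, spec: ModelSpec):
    """Constant extrapolation for spline terms: new covariate values outside
    the training range are clipped to it before the basis is evaluated (the
    basis knots live at the training extremes)."""
    if spec.specification != "correct":
        return lambda c: c
    bounds = {c: (cov[c].min(), cov[c].max()) for c in _NONLINEAR}

    def clip(c: pd.DataFrame) -> pd.DataFrame:
        c = c.copy()
        for name, (lo, hi) in bounds.items():
            c[name] = c[name].clip(lo, hi)
        return c

    return clip


def build_design(cov: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix for a spec: patsy formula for the regressions, raw
    covariates for the forest.

    For the regression models the returned frame carries patsy
    ``design_info`` so the identical basis (including spline knots fixed at
    the training data) can be rebuilt for new covariates at predict time.
    """
    _check_schema(cov)
    if spec.family == "rf":
        return cov[COVARIATE_COLUMNS].copy()
    return dmatrix(_formula(spec), cov, return_type="dataframe")


class _CostModel:
    """Base model object: covariates + positive dollar outcome + spec."""

    def __init__(self, cov: pd.DataFrame, cost, spec: ModelSpec):
        _check_schema(cov)
        cost = np.asarray(cost, dtype=float)
        if len(cov) != cost.size:
            raise ValueError("covariate table and cost vector lengths differ")
        self.cov = cov.reset_index(drop=True)
        self.cost = cost
        self.spec = spec

    @classmethod
    def from_dataset(cls, data: SimulatedDataset, spec: ModelSpec):
        return cls(data.covariates, data.cost, spec)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, spec: ModelSpec, cost_col: str = "cost"):
        if cost_col not in frame.columns:
            raise KeyError(f"no {cost_col!r} column in frame")
        return cls(frame, frame[cost_col].to_numpy(), spec)

    def fit(self) -> "CostModelResults":  # pragma: no cover - abstract
        raise NotImplementedError


class CostModelResults:
    """Fitted-model results: predictions, convergence status, diagnostics.

    ``params``/``bse`` are pandas Series for the regression models and None
    for the forest.  ``predict`` maps any covariate table with the training
    schema to one positive dollar prediction per row (conditional mean for
    GLM and RF, conditional tau-quantile for PLAQR).
    """

    def __init__(self, model, converged, predictor, params=None, bse=None, diagnostics=None):
        self.model = model
        self.spec = model.spec
        self.converged = bool(converged)
        self._predictor = predictor
        self.params = params
        self.bse = bse
        self.diagnostics = diagnostics or {}

    def predict(self, cov: pd.DataFrame) -> np.ndarray:
        if self._predictor is None:
            raise RuntimeError(
                f"{self.spec.label}: fit failed ({self.diagnostics.get('error', 'unknown')}); "
                "no predictor available"
            )
        _check_schema(cov)
        return np.asarray(self._predictor(cov), dtype=float)

    def summary(self) -> str:
        lines = [
            f"Model: {self.spec.label} (tau={self.spec.tau})" if self.spec.family == "plaqr"
            else f"Model: {self.spec.label}",
            f"Converged: {self.converged}",
        ]
        for key, val in self.diagnostics.items():
            lines.append(f"{key}: {val}")
        if self.params is not None:
            lines.append("")
            table = pd.DataFrame({"coef": self.params})
            if self.bse is not None:
                table["std err"] = self.bse
            lines.append(table.to_string(float_format=lambda v: f"{v: .5f}"))
        return "\n".join(lines)


class GammaGLM(_CostModel):
    """Gamma GLM with log link: E[cost | x] = exp(X beta).

    Fit by IRLS.  Non-convergence (iteration cap, diverging deviance, or a
    numerical failure) is recorded on the results object rather than raised,
    so a resampling harness can count failed fits.
    """

    def fit(self) -> CostModelResults:
        if np.any(self.cost <= 0):
            raise ValueError("Gamma GLM requires strictly positive costs")
        X = build_design(self.cov, self.spec)
        design_info = X.design_info
        clip = _spline_clipper(self.cov, self.spec)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(
                    self.cost, X, family=sm.families.Gamma(sm.families.links.Log())
                ).fit(maxiter=self.spec.glm_maxiter, tol=self.spec.glm_tol)
            params = pd.Series(res.params, index=X.columns)
            ok = bool(getattr(res, "converged", True)) and np.all(np.isfinite(params))
            diagnostics = {
                "iterations": len(res.fit_history.get("deviance", [])) - 1
                if hasattr(res, "fit_history") else None,
                "deviance": float(res.deviance),
            }

            def predictor(cov, _res=res, _di=design_info, _clip=clip):
                Xn = build_design_matrices([_di], _clip(cov))[0]
                return np.asarray(_res.predict(np.asarray(Xn)))

            return CostModelResults(
                self, ok, predictor,
                params=params,
                bse=pd.Series(np.asarray(res.bse), index=X.columns),
                diagnostics=diagnostics,
            )
        except Exception as err:  # numerical failure counts as non-convergence
            return CostModelResults(self, False, None, diagnostics={"error": repr(err)})


class PLAQR(_CostModel):
    """Partially linear additive quantile regression on the dollar scale.

    Minimises the check (pinball) loss at level ``tau`` over the spec's
    design matrix — linear terms plus cubic B-spline additive terms under
    the correct specification — via iteratively reweighted least squares.
    """

    def fit(self) -> CostModelResults:
        X = build_design(self.cov, self.spec)
        design_info = X.design_info
        clip = _spline_clipper(self.cov, self.spec)
        Xa = np.asarray(X)
        if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
            raise ValueError(
                f"{self.spec.label}: design matrix is rank deficient "
                f"({np.linalg.matrix_rank(Xa)} < {Xa.shape[1]} columns); "
                "remove collinear covariates"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.QuantReg(self.cost, X).fit(
                q=self.spec.tau, max_iter=self.spec.qr_max_iter
            )
        params = pd.Series(res.params, index=X.columns)

        def predictor(cov, _params=params.to_numpy(), _di=design_info, _clip=clip):
            Xn = np.asarray(build_design_matrices([_di], _clip(cov))[0])
            return Xn @ _params

        return CostModelResults(
            self, True, predictor,
            params=params,
            bse=pd.Series(np.asarray(res.bse), index=X.columns),
            diagnostics={"tau": self.spec.tau},
        )


class RandomForestCost(_CostModel):
    """Bagged regression forest on the ten raw covariates.

    Full-grown trees (unlimited depth, minimum leaf size ``rf_min_leaf``)
    on bootstrap resamples; per-tree predictions are averaged.  The number
    of candidate predictors per split (mtry) is chosen as the grid value
    minimising out-of-bag mean squared error, ties toward smaller mtry.
    x7 enters as a single integer-coded feature.
    """

    def fit(self) -> CostModelResults:
        if len(self.cov) < 2:
            raise ValueError("random forest requires at least 2 training rows")
        X = build_design(self.cov, self.spec)
        tune_seed, fit_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in SeedSequence(self.spec.seed).spawn(2)
        )
        oob_by_mtry: dict[int, float] = {}
        mtry = self.spec.rf_mtry
        if mtry is None:
            best = np.inf
            for m in self.spec.rf_mtry_grid:
                probe = RandomForestRegressor(
                    n_estimators=self.spec.rf_tune_ntree,
                    max_features=m,
                    min_samples_leaf=self.spec.rf_min_leaf,
                    bootstrap=True,
                    oob_score=True,
                    random_state=tune_seed,
                    n_jobs=1,
                ).fit(X, self.cost)
                oob_mse = float(np.mean((probe.oob_prediction_ - self.cost) ** 2))
                oob_by_mtry[m] = oob_mse
                if oob_mse < best * (1 - 1e-12):
                    best, mtry = oob_mse, m
        forest = RandomForestRegressor(
            n_estimators=self.spec.rf_ntree,
            max_features=mtry,
            min_samples_leaf=self.spec.rf_min_leaf,
            bootstrap=True,
            oob_score=True,
            random_state=fit_seed,
            n_jobs=1,
        ).fit(X, self.cost)
        oob_rmse = float(np.sqrt(np.mean((forest.oob_prediction_ - self.cost) ** 2)))

        def predictor(cov, _forest=forest):
            return _forest.predict(cov[COVARIATE_COLUMNS])

        return CostModelResults(
            self, True, predictor,
            diagnostics={
                "mtry": int(mtry),
                "oob_rmse": oob_rmse,
                "oob_mse_by_mtry": oob_by_mtry,
                "ntree": self.spec.rf_ntree,
            },
        )


_MODEL_CLASSES = {"gamma_glm": GammaGLM, "plaqr": PLAQR, "rf": RandomForestCost}


def fit_model(data: SimulatedDataset | pd.DataFrame, spec: ModelSpec) -> CostModelResults:
    """Fit the estimator named by ``spec`` to a dataset and return results."""
    cls = _MODEL_CLASSES[spec.family]
    if isinstance(data, SimulatedDataset):
        return cls.from_dataset(data, spec).fit()
    return cls.from_dataframe(data, spec).fit()


def fit_gamma_glm(data, spec: ModelSpec | None = None, **kw) -> CostModelResults:
    spec = spec or ModelSpec(family="gamma_glm", **kw)
    return fit_model(data, replace(spec, family="gamma_glm"))


def fit_plaqr(data, spec: ModelSpec | None = None, **kw) -> CostModelResults:
    spec = spec or ModelSpec(family="plaqr", **kw)
    return fit_model(data, replace(spec, family="plaqr"))


def fit_rf(data, spec: ModelSpec | None = None, **kw) -> CostModelResults:
    spec = spec or ModelSpec(family="rf", **kw)
    return fit_model(data, replace(spec, family="rf"))


def predict(results: CostModelResults, cov: pd.DataFrame) -> np.ndarray:
    """Dollar predictions of a fitted model on a covariate table."""
    return results.predict(cov)
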