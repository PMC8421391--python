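"""Enzyme kinetics fitting: Michaelis-Menten, allosteric sigmoidal, and
constrained sigmoidal dose-response models.

Organized in the statsmodels idiom: a model object is constructed from data
(``Model(x, y)`` or ``Model.from_dataframe(df)``), ``fit()`` runs the
nonlinear least squares, and the returned :class:`KineticsResults` carries
estimates, standard errors, residual diagnostics, ``predict`` and a
``summary()`` table.

Rate laws
---------
* Michaelis-Menten:        v = Vmax * S / (Km + S)
* Allosteric sigmoidal:    v = Vmax * S^h / (K_half^h + S^h)
  (h = 1 reduces exactly to Michaelis-Menten with K_half = Km); when the
  enzyme concentration is supplied, k_cat = Vmax / [E] is reported too.
* Dose-response:           A = bottom + (top - bottom) / (1 + (x/XC50)^h)
  for inhibition (A(0) = top), and the mirrored form
  A = bottom + (top - bottom) * x^h / (XC50^h + x^h) for activation
  (A(0) = bottom); both give A(XC50) = (top + bottom)/2. Top and/or bottom
  may be held fixed, as is standard when activity is normalized to 100%.

Positivity of Vmax, Km/K_half, XC50 and the Hill coefficient is enforced by
fitting on the log scale; standard errors come from the Jacobian at the
optimum and are mapped back by the delta method. Concentration units are
carried as metadata only -- nothing is converted implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "KineticsError",
    "FitFailure",
    "KineticsResults",
    "MichaelisMenten",
    "AllostericSigmoidal",
    "DoseResponse",
    "fit_michaelis_menten",
    "fit_allosteric_sigmoidal",
    "fit_dose_response",
]


class KineticsError(ValueError):
    pass


class FitFailure(KineticsError):
    """Nonlinear fit did not converge; message carries solver diagnostics."""


@dataclass
class KineticsResults:
    """Parameter estimates with uncertainties for a fitted rate law."""

    model_name: str
    params: pd.Series                 # natural-scale estimates
    bse: pd.Series                    # standard errors (delta method)
    fixed: dict                       # constrained parameters, reported as fixed
    rss: float
    df_resid: int
    cov: pd.DataFrame | None
    model: "KineticsModel"
    derived: dict = field(default_factory=dict)   # e.g. k_cat

    def predict(self, x: np.ndarray | None = None) -> np.ndarray:
        x = self.model.x if x is None else np.asarray(x, dtype=float)
        return self.model.evaluate(x, {**self.params.to_dict(), **self.fixed})

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.predict()

    def summary(self) -> str:
        lines = [f"{self.model_name} fit  (n = {len(self.model.x)}, "
                 f"RSS = {self.rss:.6g}, df = {self.df_resid})"]
        unit = self.model.meta.get("x_unit", "")
        if unit:
            lines.append(f"concentration unit: {unit}")
        lines.append(f"{'parameter':<12s}{'estimate':>14s}{'std err':>12s}")
        for name in self.params.index:
            lines.append(f"{name:<12s}{self.params[name]:>14.6g}{self.bse[name]:>12.3g}")
        for name, val in self.fixed.items():
            lines.append(f"{name:<12s}{val:>14.6g}{'(fixed)':>12s}")
        for name, (val, se) in self.derived.items():
            lines.append(f"{name:<12s}{val:>14.6g}{se:>12.3g}")
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.x, self.model.y, "o", label="data")
        lo = self.model.x[self.model.x > 0].min() if (self.model.x > 0).any() else 1e-3
        grid = np.geomspace(lo, self.model.x.max(), n_grid)
        ax.plot(grid, self.predict(grid), "-", label=self.model_name)
        ax.set_xscale("log")
        ax.set_xlabel(f"concentration ({self.model.meta.get('x_unit', 'a.u.')})")
        ax.set_ylabel("rate / activity")
        ax.legend()
        return ax


class KineticsModel:
    """Base class: holds data, defines the rate law, and runs the fit."""

    name = "kinetics"
    param_names: tuple = ()
    log_params: tuple = ()            # subset fitted on the log scale

    def __init__(self, x, y, *, meta: Mapping | None = None,
                 min_distinct: int = 4):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise KineticsError("x and y must be 1-D and equal length")
        if np.any(self.x < 0):
            raise KineticsError("concentrations must be non-negative")
        if not np.all(np.isfinite(self.y)):
            raise KineticsError("non-finite responses")
        if len(np.unique(self.x)) < min_distinct:
            raise KineticsError(f"need >= {min_distinct} distinct concentrations")
        self.meta = dict(meta or {})
        self.fixed: dict = {}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str = "concentration",
                       y: str = "rate", **kwargs) -> "KineticsModel":
        return cls(df[x].to_numpy(), df[y].to_numpy(), **kwargs)

    # subclasses implement
    def evaluate(self, x: np.ndarray, params: Mapping[str, float]) -> np.ndarray:
        raise NotImplementedError

    def start_values(self) -> dict:
        raise NotImplementedError

    # -- fitting ---------------------------------------------------------

    def _pack(self, params: Mapping[str, float]) -> np.ndarray:
        free = [p for p in self.param_names if p not in self.fixed]
        return np.array([np.log(params[p]) if p in self.log_params else params[p]
                         for p in free])

    def _unpack(self, vec: np.ndarray) -> dict:
        free = [p for p in self.param_names if p not in self.fixed]
        out = dict(self.fixed)
        for p, v in zip(free, vec):
            out[p] = float(np.exp(v)) if p in self.log_params else float(v)
        return out

    def fit(self, start: Mapping[str, float] | None = None) -> KineticsResults:
        start_full = self.start_values()
        if start:
            start_full.update(start)
        for p in self.log_params:
            if p not in self.fixed and start_full[p] <= 0:
                start_full[p] = 1e-6
        u0 = self._pack(start_full)

        def residuals(u):
            return self.y - self.evaluate(self.x, self._unpack(u))

        rss0 = float((residuals(u0) ** 2).sum())
        sol = least_squares(residuals, u0, method="lm" if len(u0) <= len(self.x)
                            else "trf", max_nfev=20000)
        if not sol.success or not np.all(np.isfinite(sol.x)):
            raise FitFailure(f"{self.name} fit did not converge: {sol.message} "
                             f"(nfev = {sol.nfev}, cost = {sol.cost:.4g})")
        params_all = self._unpack(sol.x)
        rss = float((sol.fun ** 2).sum())
        if rss > rss0 + 1e-12:
            raise FitFailure(f"{self.name} fit worsened the initialization "
                             f"(RSS {rss:.4g} > {rss0:.4g})")
        free = [p for p in self.param_names if p not in self.fixed]
        df_resid = max(len(self.x) - len(free), 1)
        s2 = rss / df_resid
        J = sol.jac
        try:
            cov_u = np.linalg.inv(J.T @ J) * s2
        except np.linalg.LinAlgError:
            cov_u = np.full((len(free), len(free)), np.nan)
        # delta method: p = exp(u) => se_p = p * se_u
        scale = np.array([params_all[p] if p in self.log_params else 1.0 for p in free])
        cov_nat = cov_u * np.outer(scale, scale)
        se = np.sqrt(np.clip(np.diag(cov_nat), 0, None))
        params = pd.Series({p: params_all[p] for p in free})
        bse = pd.Series(dict(zip(free, se)))
        res = KineticsResults(
            model_name=self.name, params=params, bse=bse, fixed=dict(self.fixed),
            rss=rss, df_resid=df_resid,
            cov=pd.DataFrame(cov_nat, index=free, columns=free), model=self,
        )
        self._add_derived(res)
        return res

    def _add_derived(self, results: KineticsResults) -> None:
        pass


class MichaelisMenten(KineticsModel):
    """v = Vmax * S / (Km + S)."""

    name = "Michaelis-Menten"
    param_names = ("Vmax", "Km")
    log_params = ("Vmax", "Km")

    def evaluate(self, x, params):
        return params["Vmax"] * x / (params["Km"] + x)

    def start_values(self):
        vmax0 = float(self.y.max())
        if vmax0 <= 0:
            raise FitFailure("all responses non-positive: saturation model undefined")
        half = vmax0 / 2.0
        above = self.x[self.y >= half]
        km0 = float(above.min()) if len(above) else float(np.median(self.x[self.x > 0]))
        return {"Vmax": vmax0, "Km": max(km0, 1e-9)}


class AllostericSigmoidal(KineticsModel):
    """v = Vmax * S^h / (K_half^h + S^h) (Hill form; h = 1 is Michaelis-Menten)."""

    name = "allosteric sigmoidal"
    param_names = ("Vmax", "Khalf", "h")
    log_params = ("Vmax", "Khalf", "h")

    def __init__(self, x, y, *, enzyme_conc: float | None = None, **kwargs):
        super().__init__(x, y, **kwargs)
        self.enzyme_conc = enzyme_conc

    def evaluate(self, x, params):
        with np.errstate(divide="ignore", invalid="ignore"):
            xh = np.where(x > 0, x ** params["h"], 0.0)
        return params["Vmax"] * xh / (params["Khalf"] ** params["h"] + xh)

    def start_values(self):
        mm = MichaelisMenten(self.x, self.y).start_values()
        return {"Vmax": mm["Vmax"], "Khalf": mm["Km"], "h": 1.0}

    def _add_derived(self, results: KineticsResults) -> None:
        if self.enzyme_conc:
            vmax = results.params.get("Vmax", self.fixed.get("Vmax"))
            se = results.bse.get("Vmax", 0.0)
            results.derived["k_cat"] = (vmax / self.enzyme_conc, se / self.enzyme_conc)


class DoseResponse(KineticsModel):
    """Sigmoidal dose-response with optional fixed top/bottom.

    ``direction`` is 'inhibition' (activity falls from top with increasing
    dose; midpoint reported as IC50) or 'activation' (activity rises from
    bottom; midpoint reported as AC50). The Hill slope h stays positive in
    both directions. A constraint that contradicts the observed trend is
    warned about, then fitted anyway.
    """

    name = "dose-response"
    param_names = ("XC50", "h", "top", "bottom")
    log_params = ("XC50", "h")

    def __init__(self, x, y, *, constraints: Mapping[str, float] | None = None,
                 direction: str = "inhibition", **kwargs):
        super().__init__(x, y, **kwargs)
        if direction not in ("inhibition", "activation"):
            raise KineticsError("direction must be 'inhibition' or 'activation'")
        self.direction = direction
        self.fixed = {k: float(v) for k, v in (constraints or {}).items()}
        bad = set(self.fixed) - {"top", "bottom", "h"}
        if bad:
            raise KineticsError(f"cannot constrain {sorted(bad)}")
        self._check_direction()

    def _check_direction(self) -> None:
        order = np.argsort(self.x)
        n = max(len(self.x) // 3, 1)
        low = self.y[order[:n]].mean()
        high = self.y[order[-n:]].mean()
        import warnings
        if self.direction == "inhibition" and high > low:
            warnings.warn("responses rise with dose but direction='inhibition'",
                          stacklevel=3)
        if self.direction == "activation" and high < low:
            warnings.warn("responses fall with dose but direction='activation'",
                          stacklevel=3)

    @property
    def midpoint_label(self) -> str:
        return "IC50" if self.direction == "inhibition" else "AC50"

    def evaluate(self, x, params):
        top, bottom, h, xc50 = (params["top"], params["bottom"],
                                params["h"], params["XC50"])
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(x > 0, x ** h / (xc50 ** h + x ** h),
                            0.0)
        if self.direction == "inhibition":
            return top + (bottom - top) * frac
        return bottom + (top - bottom) * frac

    def start_values(self):
        lo, hi = float(self.y.min()), float(self.y.max())
        pos = self.x[self.x > 0]
        return {"top": hi if self.direction == "inhibition" else hi,
                "bottom": lo,
                "h": 1.0,
                "XC50": float(np.median(pos)) if len(pos) else 1.0}

    def _add_derived(self, results: KineticsResults) -> None:
        xc50 = results.params.get("XC50")
        if xc50 is not None:
            results.derived[self.midpoint_label] = (xc50, results.bse["XC50"])


# ---------------------------------------------------------------------------
# Functional conveniences


def fit_michaelis_menten(x, y, **kwargs) -> KineticsResults:
    return MichaelisMenten(x, y, **kwargs).fit()


def fit_allosteric_sigmoidal(x, y, enzyme_conc: float | None = None,
                             **kwargs) -> KineticsResults:
    return AllostericSigmoidal(x, y, enzyme_conc=enzyme_conc, **kwargs).fit()


def fit_dose_response(x, y, constraints: Mapping[str, float] | None = None,
                      direction: str = "inhibition", **kwargs) -> KineticsResults:
    return DoseResponse(x, y, constraints=constraints, direction=direction,
                        **kwargs).fit()
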