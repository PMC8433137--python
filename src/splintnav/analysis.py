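"""Accuracy analysis: TRE covariates, the sqrt(TRE) mixed model, group lines.

The study-level analysis models the square root of the target registration
error, whose distribution is much closer to Gaussian than the raw TRE.  Fixed
effects are tracking technique, registration method and the target's distance
from the splint centroid (centered at the mean infraorbital-rim distance so
the intercept is the expected sqrt(TRE) at the orbital rim), plus their
interactions; the reference category is bone-anchored registration with
optical tracking.  Surface-based registration exists only with EM tracking,
so that cell is structurally absent and no technique:surface interaction is
estimated.

The fit is exposed statsmodels-style: :class:`SqrtTreModel` is built from a
records DataFrame and ``fit()`` returns a :class:`SqrtTreResults` carrying the
coefficient table, derived per-group intercept/slope lines and a printable
summary.  Variance estimation uses REML with a random intercept per cadaver
by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import LandmarkSet
from .simulator import (
    BONE_ANCHORED,
    EM,
    INFRAORBITAL_LABELS,
    OPTICAL,
    REGISTRATION_FREE,
    SURFACE_BASED,
)

__all__ = [
    "CovariateError",
    "DerivationError",
    "FE_TERMS",
    "REFERENCE_FIXED_EFFECTS",
    "REFERENCE_GROUP_LINES",
    "REFERENCE_OVER_2MM",
    "compute_covariates",
    "covariates_from_phantoms",
    "SqrtTreModel",
    "SqrtTreResults",
    "fit_lmm",
    "derive_group_lines",
    "fixed_effects_from_group_lines",
    "proportion_above",
    "distribution_summary",
]


class CovariateError(ValueError):
    """Raised when covariates cannot be computed (e.g. missing rim targets)."""


class DerivationError(KeyError):
    """Raised when a required fixed-effect term is absent from the table."""


#: Canonical fixed-effect term order (reference: optical bone-anchored).
FE_TERMS = [
    "intercept",
    "distance",
    "em",
    "registration_free",
    "surface_based",
    "distance:em",
    "distance:registration_free",
    "distance:surface_based",
    "em:registration_free",
    "distance:em:registration_free",
]

#: Fixed-effect estimates (estimate, standard deviation, t value) reported by
#: the cadaver accuracy study this toolkit models; sqrt(mm) scale, distance
#: terms per mm.  Used as reference input for group-line derivation checks.
REFERENCE_FIXED_EFFECTS = pd.DataFrame(
    [
        ("intercept", 0.970, 0.0348, 27.86),
        ("distance", 0.005, 0.0002, 23.07),
        ("em", -0.064, 0.0202, -3.19),
        ("registration_free", 0.188, 0.0202, 9.31),
        ("surface_based", 0.197, 0.0202, 9.78),
        ("distance:em", -0.001, 0.0003, -2.35),
        ("distance:registration_free", -0.001, 0.0003, -3.13),
        ("distance:surface_based", -0.003, 0.0003, -9.73),
        ("em:registration_free", -0.253, 0.0286, -8.87),
        ("distance:em:registration_free", 0.000, 0.0004, 0.86),
    ],
    columns=["term", "estimate", "sd", "t"],
).set_index("term")

#: Per-group intercept (sqrt(mm) at the infraorbital rim) and slope
#: (sqrt(mm) per mm) reported by the cadaver study, printed precision.
REFERENCE_GROUP_LINES = {
    (OPTICAL, BONE_ANCHORED): (0.97, 0.0049),
    (OPTICAL, REGISTRATION_FREE): (1.16, 0.0039),
    (EM, BONE_ANCHORED): (0.91, 0.0042),
    (EM, SURFACE_BASED): (1.10, 0.0013),
    (EM, REGISTRATION_FREE): (0.84, 0.0036),
}

#: Fraction of TRE measurements above 2 mm per group, as reported.
REFERENCE_OVER_2MM = {
    (OPTICAL, BONE_ANCHORED): 0.27,
    (OPTICAL, REGISTRATION_FREE): 0.41,
    (EM, BONE_ANCHORED): 0.15,
    (EM, SURFACE_BASED): 0.17,
    (EM, REGISTRATION_FREE): 0.11,
}


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------


def compute_covariates(
    records: pd.DataFrame,
    targets: LandmarkSet,
    splint_centroid,
    infraorbital_labels=tuple(INFRAORBITAL_LABELS),
) -> pd.DataFrame:
    """Attach distance covariates and sqrt(TRE) to a TRE records table.

    ``target_distance_mm`` is the distance of each (true) target position to
    the splint centroid; ``centered_distance_mm`` subtracts the mean distance
    of the infraorbital-rim targets so the model intercept refers to accuracy
    at the rim.  ``targets`` and ``splint_centroid`` must share one frame.
    """
    missing = set(infraorbital_labels) - set(targets.labels)
    if missing:
        raise CovariateError(
            f"infraorbital labels {sorted(missing)} not present in target set"
        )
    centroid = np.asarray(splint_centroid, dtype=float).reshape(3)
    dist = {
        lab: float(np.linalg.norm(xyz - centroid))
        for lab, xyz in zip(targets.labels, targets.coordinates)
    }
    rim_mean = float(np.mean([dist[lab] for lab in infraorbital_labels]))
    unknown = set(records["target"]) - set(dist)
    if unknown:
        raise CovariateError(f"records contain unknown targets: {sorted(unknown)}")
    out = records.copy()
    out["target_distance_mm"] = out["target"].map(dist)
    out["centered_distance_mm"] = out["target_distance_mm"] - rim_mean
    out["sqrt_tre"] = np.sqrt(out["tre_mm"].to_numpy())
    return out


def covariates_from_phantoms(records: pd.DataFrame, phantoms) -> pd.DataFrame:
    """Attach covariates per cadaver, each against its own phantom geometry.

    Target distances and the infraorbital-rim centering are computed from each
    cadaver's own target layout and splint centroid, mirroring how per-subject
    geometry enters the pooled study analysis.
    """
    parts = []
    for cadaver, sub in records.groupby("cadaver"):
        ph = phantoms[int(cadaver)]
        parts.append(compute_covariates(sub, ph.targets, ph.splint_centroid_patient))
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------


def _design_matrix(df: pd.DataFrame) -> pd.DataFrame:
    d = df["centered_distance_mm"].to_numpy(dtype=float)
    em = (df["technique"] == EM).to_numpy(dtype=float)
    rf = (df["method"] == REGISTRATION_FREE).to_numpy(dtype=float)
    sb = (df["method"] == SURFACE_BASED).to_numpy(dtype=float)
    cols = {
        "intercept": np.ones(len(df)),
        "distance": d,
        "em": em,
        "registration_free": rf,
        "surface_based": sb,
        "distance:em": d * em,
        "distance:registration_free": d * rf,
        "distance:surface_based": d * sb,
        "em:registration_free": em * rf,
        "distance:em:registration_free": d * em * rf,
    }
    x = pd.DataFrame(cols, index=df.index)
    # Drop columns for cells that are structurally absent in this dataset
    # (identically zero), e.g. no surface-based terms in a two-arm design.
    keep = [c for c in x.columns if c == "intercept" or np.any(x[c].to_numpy() != 0)]
    return x[keep]


@dataclass
class SqrtTreResults:
    """Fitted sqrt(TRE) mixed model: coefficient table and derived lines."""

    fe_table: pd.DataFrame  # index term; columns estimate, sd, t
    converged: bool
    method: str  # "REML" or "ML"
    random_effects: str
    n_obs: int
    scale: float
    group_var: float
    singular_terms: list[str]
    diagnostics: str = ""

    @property
    def params(self) -> pd.Series:
        return self.fe_table["estimate"]

    def group_lines(self) -> pd.DataFrame:
        return derive_group_lines(self.fe_table)

    def summary(self) -> str:
        lines = [
            "sqrt(TRE) linear mixed model "
            f"({self.method}, random effects: {self.random_effects})",
            f"n obs: {self.n_obs}   residual var: {self.scale:.5f}   "
            f"cadaver intercept var: {self.group_var:.5f}",
            f"converged: {self.converged}"
            + (f"   [{self.diagnostics}]" if self.diagnostics else ""),
            "",
            self.fe_table.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            "Derived group lines (intercept at infraorbital rim, slope per mm):",
            self.group_lines().to_string(index=False),
        ]
        if self.singular_terms:
            lines.append(f"singular terms: {self.singular_terms}")
        return "\n".join(lines)


class SqrtTreModel:
    """Mixed model for sqrt(TRE) ~ technique * method * centered distance.

    Parameters
    ----------
    data : DataFrame
        TRE records with columns ``technique``, ``method``, ``cadaver``,
        ``centered_distance_mm`` and ``sqrt_tre`` (see
        :func:`compute_covariates`).
    random_effects : str
        ``"cadaver"`` (random intercept per cadaver, default) or
        ``"cadaver+observer+target"`` adding observer and target variance
        components within cadaver.
    reml : bool
        Restricted maximum likelihood (default) or plain ML.
    """

    def __init__(self, data: pd.DataFrame, random_effects: str = "cadaver",
                 reml: bool = True) -> None:
        required = {"technique", "method", "cadaver", "centered_distance_mm", "sqrt_tre"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"records are missing columns: {sorted(missing)}")
        if random_effects not in ("cadaver", "cadaver+observer+target"):
            raise ValueError(f"unknown random-effects spec {random_effects!r}")
        for col in ("technique", "method"):
            if data[col].nunique() < 2 and data["method"].nunique() * data["technique"].nunique() < 2:
                raise ValueError("need at least 2 modeled factor levels")
        self.data = data.reset_index(drop=True)
        self.random_effects = random_effects
        self.reml = reml
        self.exog = _design_matrix(self.data)
        self.endog = self.data["sqrt_tre"].to_numpy(dtype=float)

    def fit(self) -> SqrtTreResults:
        x = self.exog
        y = self.endog
        # Degenerate data: constant response has an exact trivial solution.
        if np.ptp(y) < 1e-12:
            est = pd.Series(0.0, index=x.columns)
            est["intercept"] = float(y[0]) if len(y) else 0.0
            table = pd.DataFrame(
                {"estimate": est, "sd": 0.0, "t": np.nan}
            )
            return SqrtTreResults(
                table, True, "REML" if self.reml else "ML", self.random_effects,
                len(y), 0.0, 0.0, [], diagnostics="zero-variance response",
            )

        rank = np.linalg.matrix_rank(x.to_numpy())
        singular: list[str] = []
        if rank < x.shape[1]:
            # Identify and drop aliased columns, reporting them explicitly.
            q, r = np.linalg.qr(x.to_numpy())
            diag = np.abs(np.diag(r))
            bad = diag < 1e-8 * diag.max()
            singular = [c for c, b in zip(x.columns, bad) if b]
            x = x.drop(columns=singular)

        import statsmodels.api as sm

        groups = self.data["cadaver"].to_numpy()
        kwargs = {}
        if self.random_effects == "cadaver+observer+target":
            from statsmodels.regression.mixed_linear_model import VCSpec

            levels = pd.unique(groups)
            names, colnames, mats = [], [], []
            for factor in ("observer", "target"):
                dummies = pd.get_dummies(self.data[factor], dtype=float)
                names.append(factor)
                colnames.append([list(dummies.columns)] * len(levels))
                mats.append([dummies[groups == g].to_numpy() for g in levels])
            kwargs["exog_vc"] = VCSpec(names, colnames, mats)

        model = sm.MixedLM(y, x.to_numpy(), groups=groups, **kwargs)
        converged = True
        diag_msg = ""
        k = x.shape[1]

        def sane(candidate) -> bool:
            # Guards against degenerate optima where a singular random-effects
            # covariance lets fixed effects be absorbed by unpenalized BLUPs
            # (symptom: absurd standard errors).
            bse = np.asarray(candidate.bse)[:k]
            return bool(np.all(np.isfinite(bse)) and bse.max() < 1e3)

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = None
            fallback = None
            for method in (None, "powell", "lbfgs"):
                try:
                    candidate = model.fit(
                        reml=self.reml, **({} if method is None else {"method": method})
                    )
                except Exception:
                    continue
                if sane(candidate):
                    if fallback is None:
                        fallback = candidate
                    if getattr(candidate, "converged", True):
                        res = candidate
                        break
            if res is None:
                res = fallback
            if res is None:
                raise RuntimeError("mixed-model fit failed with every optimizer")
            messages = {str(w.message) for w in caught}
        # statsmodels may retry internally; trust the final converged flag and
        # keep boundary-of-parameter-space notes as diagnostics only.
        converged = bool(getattr(res, "converged", True))
        if not converged:
            diag_msg = "optimizer reported non-convergence"
        else:
            boundary = [m for m in messages if "boundary" in m.lower()]
            diag_msg = boundary[0] if boundary else ""

        est = pd.Series(res.params[:k], index=x.columns)
        se = pd.Series(res.bse[:k], index=x.columns)
        table = pd.DataFrame(
            {"estimate": est, "sd": se, "t": est / se}
        ).reindex(self.exog.columns.tolist())
        group_var = float(np.atleast_2d(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
        return SqrtTreResults(
            table, converged, "REML" if self.reml else "ML", self.random_effects,
            len(y), float(res.scale), group_var, singular, diag_msg,
        )


def fit_lmm(records: pd.DataFrame, random_effects: str = "cadaver",
            reml: bool = True) -> SqrtTreResults:
    """Convenience wrapper: build :class:`SqrtTreModel` and fit it."""
    return SqrtTreModel(records, random_effects=random_effects, reml=reml).fit()


# ---------------------------------------------------------------------------
# Group lines
# ---------------------------------------------------------------------------

_GROUP_TERMS = {
    (OPTICAL, BONE_ANCHORED): ([], []),
    (OPTICAL, REGISTRATION_FREE): (
        ["registration_free"], ["distance:registration_free"]),
    (EM, BONE_ANCHORED): (["em"], ["distance:em"]),
    (EM, SURFACE_BASED): (
        ["em", "surface_based"], ["distance:em", "distance:surface_based"]),
    (EM, REGISTRATION_FREE): (
        ["em", "registration_free", "em:registration_free"],
        ["distance:em", "distance:registration_free",
         "distance:em:registration_free"]),
}


def fixed_effects_from_group_lines(group_lines: dict) -> pd.Series:
    """Invert the group-line map: term-space coefficients from per-group lines.

    Exact inverse of :func:`derive_group_lines` (the map is linear and
    bijective between the five group lines and the ten model terms).
    """
    g = {k: tuple(map(float, v)) for k, v in group_lines.items()}
    ob, orf = g[(OPTICAL, BONE_ANCHORED)], g[(OPTICAL, REGISTRATION_FREE)]
    eb, es, erf = (g[(EM, BONE_ANCHORED)], g[(EM, SURFACE_BASED)],
                   g[(EM, REGISTRATION_FREE)])
    out = {}
    for i, prefix in ((0, ""), (1, "distance:")):
        out["distance" if prefix else "intercept"] = ob[i]
        out[f"{prefix}em"] = eb[i] - ob[i]
        out[f"{prefix}registration_free"] = orf[i] - ob[i]
        out[f"{prefix}surface_based"] = es[i] - eb[i]
        out[f"{prefix}em:registration_free"] = (erf[i] - eb[i]) - (orf[i] - ob[i])
    return pd.Series(out).reindex(FE_TERMS)


def derive_group_lines(fixed_effects) -> pd.DataFrame:
    """Recalculate per-group intercept/slope lines from fixed-effect estimates.

    Each technique x method combination's intercept (sqrt(mm) at the
    infraorbital rim) is the sum of the applicable main effects and
    interactions on top of the model intercept; slopes add the corresponding
    distance interactions to the distance term.  Reported columns round to the
    study's printed precision (2 decimals for intercepts, 4 for slopes).
    """
    if isinstance(fixed_effects, pd.DataFrame):
        est = fixed_effects["estimate"]
    else:
        est = pd.Series(dict(fixed_effects))

    def term(name: str) -> float:
        if name not in est.index or pd.isna(est[name]):
            raise DerivationError(f"fixed-effect term {name!r} missing from table")
        return float(est[name])

    rows = []
    for (technique, method), (int_terms, slope_terms) in _GROUP_TERMS.items():
        intercept = term("intercept") + sum(term(t) for t in int_terms)
        slope = term("distance") + sum(term(t) for t in slope_terms)
        rows.append(
            dict(
                technique=technique,
                method=method,
                intercept=intercept,
                slope=slope,
                intercept_reported=round(intercept, 2),
                slope_reported=round(slope, 4),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distribution summaries
# ---------------------------------------------------------------------------


def proportion_above(records: pd.DataFrame, threshold_mm: float) -> pd.DataFrame:
    """Fraction of TRE measurements strictly above a threshold, per group."""
    if threshold_mm <= 0:
        raise ValueError("threshold must be positive")
    rows = []
    for (technique, method), grp in records.groupby(["technique", "method"]):
        tre = grp["tre_mm"].to_numpy()
        rows.append(
            dict(
                technique=technique,
                method=method,
                fraction=float(np.mean(tre > threshold_mm)),
                n=len(tre),
            )
        )
    return pd.DataFrame(rows)


def distribution_summary(records: pd.DataFrame, transform: str = "identity") -> dict:
    """Histogram (Freedman-Diaconis bins) + Gaussian KDE per group.

    ``transform`` selects the summarized variable: raw TRE (``"identity"``) or
    its square root (``"sqrt"``).  Groups with a single record omit the
    density.  Skewness of both TRE and sqrt(TRE) is always reported, since the
    square-root transform's normalizing effect is the reason the model works
    on that scale.
    """
    if transform not in ("identity", "sqrt"):
        raise ValueError("transform must be 'identity' or 'sqrt'")
    out: dict = {}
    for (technique, method), grp in records.groupby(["technique", "method"]):
        tre = grp["tre_mm"].to_numpy(dtype=float)
        values = np.sqrt(tre) if transform == "sqrt" else tre
        entry: dict = {
            "n": len(values),
            "transform": transform,
            "skewness_tre": float(stats.skew(tre)) if len(tre) > 2 else np.nan,
            "skewness_sqrt_tre": (
                float(stats.skew(np.sqrt(tre))) if len(tre) > 2 else np.nan
            ),
        }
        edges = np.histogram_bin_edges(values, bins="fd" if len(values) > 1 else 1)
        counts, edges = np.histogram(values, bins=edges)
        entry["bin_edges"] = edges
        entry["counts"] = counts
        if len(values) >= 2 and np.ptp(values) > 0:
            kde = stats.gaussian_kde(values, bw_method="silverman")
            bw = kde.factor * values.std(ddof=1)
            grid = np.linspace(values.min() - 5 * bw, values.max() + 5 * bw, 512)
            entry["kde_grid"] = grid
            entry["kde_density"] = kde(grid)
        elif len(values) >= 2:
            # Point-mass data: density collapses to the common value.
            entry["kde_grid"] = np.array([values[0]])
            entry["kde_density"] = np.array([np.inf])
        out[(technique, method)] = entry
    return out
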