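"""The three inference stages for gesture-driven emotional resonance.

1. **Crescendo model** (:class:`CrescendoModel`): does gesture expressivity
   rise from story onset toward the climax?  A linear mixed model of
   ``G_expressivity`` on ``G_position_rel`` with a random slope per
   narrator-within-recording (falling back to random intercepts on singular
   fit), tested by a likelihood-ratio test against the null without the
   position term, with Nakagawa's conditional pseudo-R^2 and the share of
   narrators whose fitted slope is positive.

2. **Arousal model** (:class:`ArousalModel`): does expressivity predict
   *specific* skin-conductance responses?  A mixed-effects logistic
   regression of the per-(gesture, participant) specific-response indicator
   on ``G_expressivity`` with crossed random intercepts for participant and
   recording (Laplace ML, :mod:`resogest.glmm`), likelihood-ratio tested
   against the null without expressivity; conditional pseudo-R^2 uses the
   logit-link residual variance pi^2 / 3.

3. **Resonance forest** (:class:`ResonanceForest`): how important is each of
   13 predictors (the seven expressivity components plus quote co-occurrence,
   sentiment, protagonist, group composition, group size, recency) for
   gesture-level resonance?  A bagged-tree classifier (1,500 trees, 3
   candidate predictors per split) with out-of-bag majority-vote predictions,
   OOB permutation importance (mean decrease in accuracy), exact one-tailed
   binomial fit test against the majority-class baseline, traditional and
   McFadden R^2 on OOB vote shares, and individual-conditional-expectation
   (ICE) curves whose per-group means equal partial-dependence curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import LogisticMixedModel, LogisticMixedResults

__all__ = [
    "LRTResult",
    "CrescendoModel",
    "CrescendoResults",
    "ArousalModel",
    "ArousalResults",
    "ResonanceForest",
    "ResonanceForestResults",
    "ICECurveSet",
    "DEFAULT_PREDICTORS",
    "classification_fit_metrics",
    "fit_crescendo",
    "fit_arousal",
    "fit_resonance_forest",
]


@dataclass
class LRTResult:
    """Likelihood-ratio test of a full against a nested null model."""

    statistic: float
    df: int
    pvalue: float
    llf_full: float
    llf_null: float
    full_desc: str
    null_desc: str


# ---------------------------------------------------------------------------
# RQ1: crescendo linear mixed model


@dataclass
class CrescendoResults:
    fe_params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cov_re: pd.DataFrame | None
    resid_var: float | None
    llf: float | None
    lrt: LRTResult | None
    pseudo_r2_conditional: float | None
    group_slopes: pd.Series | None
    frac_positive_slope: float | None
    random_structure: str  # "slopes" | "intercepts" | "degenerate"
    nobs: int
    n_groups: int
    model: "CrescendoModel" = field(repr=False, default=None)

    @property
    def degenerate(self) -> bool:
        return self.random_structure == "degenerate"

    def summary(self) -> str:
        lines = [
            "Crescendo model: linear mixed model (REML estimates, ML LRT)",
            f"  nobs = {self.nobs}, groups = {self.n_groups}, "
            f"random structure = {self.random_structure}",
            "  Fixed effects:",
        ]
        for name in self.fe_params.index:
            lines.append(
                f"    {name:<20s} {self.fe_params[name]:10.4f}  "
                f"SE {self.bse[name]:8.4f}  t {self.tvalues[name]:7.3f}  "
                f"p {self.pvalues[name]:9.3g}"
            )
        if self.lrt is not None:
            lines.append(
                f"  LRT vs null without position: chi2({self.lrt.df}) = "
                f"{self.lrt.statistic:.3f}, p = {self.lrt.pvalue:.4g}"
            )
        r2 = ("undefined" if self.pseudo_r2_conditional is None
              else f"{self.pseudo_r2_conditional:.3f}")
        lines.append(f"  Conditional pseudo-R2 (Nakagawa): {r2}")
        if self.frac_positive_slope is not None:
            lines.append(
                f"  Share of narrators with positive slope: "
                f"{100 * self.frac_positive_slope:.0f}%"
            )
        return "\n".join(lines)


class CrescendoModel:
    """Expressivity ~ relative position, random slope per narrator ID.

    ``table`` is a per-gesture feature table; the grouping ID combines
    narrator and recording.  Requires >= 2 groups and >= 10 rows.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        response: str = "G_expressivity",
        predictor: str = "G_position_rel",
        group: str | None = None,
    ):
        self.table = table.reset_index(drop=True)
        self.response = response
        self.predictor = predictor
        if group is None:
            self.groups = (
                self.table["recording_id"].astype(str)
                + ":" + self.table["narrator_id"].astype(str)
            )
        else:
            self.groups = self.table[group].astype(str)
        if len(self.table) < 10:
            raise ValueError("need at least 10 gestures to fit")
        if self.groups.nunique() < 2:
            raise ValueError("need at least 2 narrator groups to fit")

    def _mixedlm(self, with_predictor: bool, re_slopes: bool, reml: bool):
        import statsmodels.api as sm

        endog = self.table[self.response].astype(float)
        # fit on the standardized predictor: the procedure (including the
        # singular-fit check and the LRT) is then invariant to affine
        # rescaling of the position covariate; estimates are transformed
        # back for reporting
        z = self._standardized()
        exog = pd.DataFrame({"Intercept": np.ones(len(endog))})
        if with_predictor:
            exog[self.predictor] = z
        exog_re = pd.DataFrame({"Intercept": np.ones(len(endog))})
        if re_slopes:
            exog_re[self.predictor] = z
        model = sm.MixedLM(endog, exog, groups=self.groups, exog_re=exog_re)
        # statsmodels' default gradient optimizer occasionally stalls short
        # of the optimum on these small variance surfaces; keep the better
        # of the default and a Powell fit so LRTs are stable
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = []
            for method in (None, "powell"):
                try:
                    f = (model.fit(reml=reml, method=method) if method
                         else model.fit(reml=reml))
                    if np.isfinite(float(f.llf)):
                        fits.append(f)
                except (np.linalg.LinAlgError, ValueError):
                    continue
        if not fits:
            raise RuntimeError(
                "mixed linear model failed to converge with either optimizer"
            )
        return max(fits, key=lambda f: float(f.llf))

    def _standardized(self) -> np.ndarray:
        x = self.table[self.predictor].astype(float).values
        m, s = float(np.mean(x)), float(np.std(x))
        if s == 0.0:
            raise ValueError(
                f"predictor {self.predictor!r} is constant; cannot fit"
            )
        self._x_loc, self._x_scale = m, s
        return (x - m) / s

    @staticmethod
    def _singular(fit) -> bool:
        """Boundary fit: the RE covariance has a (near-)zero direction.

        Decided on the eigenvalue spectrum alone; the optimizer's converged
        flag is too volatile at variance boundaries to key the model
        structure on.
        """
        if not np.isfinite(float(fit.llf)):
            return True
        try:
            ev = np.linalg.eigvalsh(np.asarray(fit.cov_re, dtype=float))
        except np.linalg.LinAlgError:
            return True
        if ev.size == 0:
            return True
        return bool(ev.min() <= 1e-6 * max(ev.max(), 1e-12))

    def fit(self) -> CrescendoResults:
        y = self.table[self.response].astype(float)
        if float(y.var()) == 0.0:
            idx = ["Intercept", self.predictor]
            zero = pd.Series([float(y.iloc[0]), 0.0], index=idx)
            return CrescendoResults(
                fe_params=zero,
                bse=pd.Series([0.0, 0.0], index=idx),
                tvalues=pd.Series([np.nan, 0.0], index=idx),
                pvalues=pd.Series([np.nan, 1.0], index=idx),
                cov_re=None, resid_var=None, llf=None, lrt=None,
                pseudo_r2_conditional=None, group_slopes=None,
                frac_positive_slope=None, random_structure="degenerate",
                nobs=len(y), n_groups=self.groups.nunique(), model=self,
            )

        re_slopes = True
        fit_reml = self._mixedlm(True, re_slopes, reml=True)
        if self._singular(fit_reml):
            re_slopes = False
            fit_reml = self._mixedlm(True, re_slopes, reml=True)

        fit_ml_full = self._mixedlm(True, re_slopes, reml=False)
        fit_ml_null = self._mixedlm(False, re_slopes, reml=False)
        if not (np.isfinite(fit_ml_full.llf)
                and np.isfinite(fit_ml_null.llf)) and re_slopes:
            # slope-variance boundary can defeat the ML optimizer even when
            # the REML fit looked fine; drop to random intercepts
            re_slopes = False
            fit_reml = self._mixedlm(True, re_slopes, reml=True)
            fit_ml_full = self._mixedlm(True, re_slopes, reml=False)
            fit_ml_null = self._mixedlm(False, re_slopes, reml=False)
        df = len(fit_ml_full.fe_params) - len(fit_ml_null.fe_params)
        stat = max(0.0, 2.0 * (fit_ml_full.llf - fit_ml_null.llf))
        slope_re = "random slopes" if re_slopes else "random intercepts"
        lrt = LRTResult(
            statistic=stat, df=df, pvalue=float(stats.chi2.sf(stat, df)),
            llf_full=float(fit_ml_full.llf), llf_null=float(fit_ml_null.llf),
            full_desc=(
                f"{self.response} ~ 1 + {self.predictor}, {slope_re} by ID"
            ),
            null_desc=f"{self.response} ~ 1, {slope_re} by ID",
        )

        fe_z = fit_reml.fe_params
        names = list(fe_z.index)
        cov_re_z = np.asarray(fit_reml.cov_re, dtype=float)

        # Nakagawa decomposition (variances are invariant to the
        # standardization, so compute in fitting units)
        zx = self._standardized()
        Xz = np.column_stack([np.ones(len(y)), zx])
        var_f = float(np.var(Xz @ fe_z.values))
        Zre = Xz if re_slopes else np.ones((len(y), 1))
        var_re = float(np.mean(np.sum((Zre @ cov_re_z) * Zre, axis=1)))
        resid = float(fit_reml.scale)
        denom = var_f + var_re + resid
        r2c = (var_f + var_re) / denom if denom > 0 else None

        # back-transform estimates from standardized to raw predictor units
        m, s = self._x_loc, self._x_scale
        T = np.array([[1.0, -m / s], [0.0, 1.0 / s]])
        fe = pd.Series(T @ fe_z.values, index=names)
        cov_fe_z = np.asarray(fit_reml.cov_params(), dtype=float)[
            : len(names), : len(names)
        ]
        cov_fe = T @ cov_fe_z @ T.T
        bse = pd.Series(np.sqrt(np.diag(cov_fe)), index=names)
        cov_re = pd.DataFrame(
            T @ cov_re_z @ T.T if re_slopes else cov_re_z,
            index=names[: cov_re_z.shape[0]],
            columns=names[: cov_re_z.shape[0]],
        )

        # per-group slopes: fixed slope + conditional-mode deviation
        fe_slope_z = float(fe_z[self.predictor])
        try:
            ranef = fit_reml.random_effects
        except (ValueError, np.linalg.LinAlgError):
            # singular RE covariance: conditional modes are unavailable,
            # so every group inherits the fixed slope
            ranef = {g: {} for g in sorted(self.groups.unique())}
        if re_slopes:
            devs = {
                g: float(re_vals.get(self.predictor, 0.0))
                for g, re_vals in ranef.items()
            }
        else:
            devs = {g: 0.0 for g in ranef}
        group_slopes = pd.Series(
            {g: (fe_slope_z + d) / s for g, d in devs.items()}
        ).sort_index()
        frac_pos = float(np.mean(group_slopes.values > 0))

        # Wald t-tests from the REML fit (z treated as t at large df)
        tvals = fe / bse
        pvals = pd.Series(
            2 * stats.norm.sf(np.abs(tvals.values)), index=fe.index
        )
        return CrescendoResults(
            fe_params=fe, bse=bse, tvalues=tvals, pvalues=pvals,
            cov_re=cov_re, resid_var=resid, llf=float(fit_ml_full.llf),
            lrt=lrt, pseudo_r2_conditional=r2c, group_slopes=group_slopes,
            frac_positive_slope=frac_pos,
            random_structure="slopes" if re_slopes else "intercepts",
            nobs=len(y), n_groups=self.groups.nunique(), model=self,
        )


# ---------------------------------------------------------------------------
# RQ2: arousal mixed logistic model


@dataclass
class ArousalResults:
    fe_params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    sigmas: pd.Series  # random-intercept SDs per grouping factor
    llf: float
    lrt: LRTResult
    pseudo_r2_conditional: float
    random_effects: dict[str, pd.Series]
    nobs: int
    converged: bool
    model: "ArousalModel" = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Arousal model: mixed logistic regression (Laplace ML)",
            f"  nobs = {self.nobs}, logLik = {self.llf:.3f}, "
            f"converged = {self.converged}",
            "  Fixed effects:",
        ]
        for name in self.fe_params.index:
            lines.append(
                f"    {name:<20s} {self.fe_params[name]:10.4f}  "
                f"SE {self.bse[name]:8.4f}  z {self.zvalues[name]:7.3f}  "
                f"p {self.pvalues[name]:9.3g}"
            )
        for name in self.sigmas.index:
            lines.append(
                f"  Random intercept SD ({name}): {self.sigmas[name]:.4f}"
            )
        lines.append(
            f"  LRT vs null without expressivity: chi2({self.lrt.df}) = "
            f"{self.lrt.statistic:.3f}, p = {self.lrt.pvalue:.4g}"
        )
        lines.append(
            f"  Conditional pseudo-R2 (logit residual pi^2/3): "
            f"{self.pseudo_r2_conditional:.3f}"
        )
        return "\n".join(lines)


class ArousalModel:
    """Specific-response indicator ~ expressivity, crossed random
    intercepts for participant and recording.

    ``response_table`` is the long per-(gesture, participant) table produced
    by :func:`resogest.eda.build_response_table`.
    """

    def __init__(
        self,
        response_table: pd.DataFrame,
        response: str = "EDA_specific",
        predictor: str = "G_expressivity",
        participant: str = "participant_id",
        recording: str = "recording_id",
    ):
        self.table = response_table.reset_index(drop=True)
        self.response = response
        self.predictor = predictor
        self.participant = participant
        self.recording = recording
        y = self.table[response]
        if y.nunique() < 2:
            raise ValueError(
                f"outcome {response!r} has a single class; cannot fit"
            )

    def fit(self) -> ArousalResults:
        y = self.table[self.response].astype(int).values
        x = self.table[self.predictor].astype(float).values
        groups = {
            "participant": self.table[self.participant].astype(str).values,
            "recording": self.table[self.recording].astype(str).values,
        }
        names = ["Intercept", self.predictor]
        X_full = np.column_stack([np.ones_like(x), x])
        full = LogisticMixedModel(y, X_full, groups, names).fit()
        null = LogisticMixedModel(
            y, X_full[:, :1], groups, ["Intercept"]
        ).fit(compute_se=False)
        stat = max(0.0, 2.0 * (full.llf - null.llf))
        lrt = LRTResult(
            statistic=stat, df=1, pvalue=float(stats.chi2.sf(stat, 1)),
            llf_full=full.llf, llf_null=null.llf,
            full_desc=(
                f"{self.response} ~ 1 + {self.predictor} + "
                "(1|participant) + (1|recording)"
            ),
            null_desc=(
                f"{self.response} ~ 1 + (1|participant) + (1|recording)"
            ),
        )
        var_f = float(np.var(X_full @ full.params))
        var_re = float(np.sum(full.sigmas ** 2))
        r2c = (var_f + var_re) / (var_f + var_re + np.pi ** 2 / 3)
        fe = pd.Series(full.params, index=names)
        bse = pd.Series(full.bse, index=names)
        z = fe / bse
        return ArousalResults(
            fe_params=fe, bse=bse, zvalues=z,
            pvalues=pd.Series(2 * stats.norm.sf(np.abs(z.values)),
                              index=names),
            sigmas=pd.Series(full.sigmas, index=full.group_names),
            llf=full.llf, lrt=lrt, pseudo_r2_conditional=float(r2c),
            random_effects=full.random_effects, nobs=full.nobs,
            converged=full.converged, model=self,
        )


# ---------------------------------------------------------------------------
# RQ3: resonance random forest


def classification_fit_metrics(y, prob, pred) -> dict:
    """Fit metrics for binary out-of-bag predictions.

    - ``accuracy`` of the class predictions and the ``baseline`` majority
      rate they must beat;
    - ``binom_pvalue``: exact one-tailed binomial test of the correct count
      against the majority-class rate;
    - ``r2_traditional``: 1 - SSE/SST of the predicted probabilities against
      the 0/1 outcome (None when SST = 0);
    - ``r2_mcfadden``: 1 - ll_model/ll_null with Bernoulli log-likelihoods,
      probabilities clipped to [1e-6, 1 - 1e-6].
    """
    y = np.asarray(y, dtype=float)
    prob = np.asarray(prob, dtype=float)
    pred = np.asarray(pred, dtype=int)
    n = y.size
    base = float(max(np.mean(y), 1.0 - np.mean(y)))
    k = int(np.sum(pred == y))
    binom_p = float(stats.binomtest(k, n, base,
                                    alternative="greater").pvalue)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2t = (1.0 - float(np.sum((y - prob) ** 2)) / sst) if sst > 0 else None
    p_clip = np.clip(prob, 1e-6, 1 - 1e-6)
    ll_model = float(np.sum(y * np.log(p_clip)
                            + (1 - y) * np.log(1 - p_clip)))
    p0 = float(np.clip(np.mean(y), 1e-6, 1 - 1e-6))
    ll_null = float(np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0)))
    r2m = 1.0 - ll_model / ll_null if ll_null != 0 else np.nan
    return {
        "accuracy": float(np.mean(pred == y)),
        "baseline": base,
        "binom_pvalue": binom_p,
        "r2_traditional": r2t,
        "r2_mcfadden": float(r2m),
    }


#: The 13 resonance predictors: seven expressivity components plus six
#: contextual covariates.
DEFAULT_PREDICTORS = [
    "SZ", "FO", "CV", "SL", "HO", "MA", "ND",
    "G_quote", "Sentiment", "protagonist", "group_compose", "group_size",
    "recency",
]


@dataclass
class ICECurveSet:
    """Individual-conditional-expectation curves for one predictor.

    ``values[i, j]`` is the predicted resonance probability of record ``i``
    with the predictor forced to ``grid[j]`` and everything else at the
    record's observed values.  The mean over records at each grid point is
    the partial-dependence curve.
    """

    predictor: str
    grid: np.ndarray
    values: np.ndarray  # (n_records, n_grid)
    categorical: bool

    @property
    def pdp(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def plot(self, ax=None, max_curves: int = 200, color="0.6"):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        xs = (np.arange(len(self.grid)) if self.categorical
              else np.asarray(self.grid, dtype=float))
        step = max(1, self.values.shape[0] // max_curves)
        for row in self.values[::step]:
            ax.plot(xs, row, color=color, lw=0.5, alpha=0.5)
        ax.plot(xs, self.pdp, color="C1", lw=2.5, label="mean (PDP)")
        if self.categorical:
            ax.set_xticks(xs)
            ax.set_xticklabels([str(g) for g in self.grid])
        ax.set_xlabel(self.predictor)
        ax.set_ylabel("P(resonance)")
        ax.legend(frameon=False)
        return ax


@dataclass
class ResonanceForestResults:
    n_trees: int
    mtry: int
    seed: int
    outcome: str
    predictors: list[str]
    oob_prob: np.ndarray  # OOB vote share for the positive class
    oob_pred: np.ndarray
    oob_accuracy: float
    baseline_rate: float
    binom_pvalue: float
    r2_traditional: float | None
    r2_mcfadden: float
    n_never_oob: int
    model: "ResonanceForest" = field(repr=False, default=None)

    def permutation_importance(
        self, n_repeats: int = 10, seed: int | None = None
    ) -> pd.DataFrame:
        """OOB permutation importance: mean decrease in OOB majority-vote
        accuracy when a predictor's column(s) are permuted, averaged over
        ``n_repeats`` permutations; one row per predictor, sorted by
        importance.  One-hot blocks of a categorical predictor are permuted
        jointly so importance is reported per original variable."""
        return self.model._permutation_importance(self, n_repeats, seed)

    def ice_curves(self, predictor: str, grid=None,
                   n_grid: int = 20) -> ICECurveSet:
        return self.model._ice_curves(predictor, grid, n_grid)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Forest-predicted resonance probability for feature-table rows."""
        return self.model._predict_proba(table)

    def plot_importance(self, importance: pd.DataFrame | None = None,
                        ax=None):
        """Dot chart of permutation importances (computed if not given)."""
        import matplotlib.pyplot as plt

        if importance is None:
            importance = self.permutation_importance()
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4.5))
        imp = importance.sort_values("importance")
        ax.plot(imp["importance"], imp["predictor"], "o", color="C0")
        ax.axvline(0.0, color="0.7", lw=0.8)
        ax.set_xlabel("mean decrease in OOB accuracy")
        ax.grid(axis="y", ls=":", lw=0.5)
        return ax

    def summary(self) -> str:
        r2t = ("undefined" if self.r2_traditional is None
               else f"{self.r2_traditional:.3f}")
        return "\n".join([
            f"Resonance forest: {self.n_trees} trees, mtry = {self.mtry}, "
            f"seed = {self.seed}",
            f"  outcome = {self.outcome}, n = {len(self.oob_prob)}, "
            f"predictors = {len(self.predictors)}",
            f"  OOB accuracy = {self.oob_accuracy:.3f} "
            f"(baseline {self.baseline_rate:.3f}), exact one-tailed "
            f"binomial p = {self.binom_pvalue:.3g}",
            f"  traditional R2 = {r2t}, McFadden R2 = "
            f"{self.r2_mcfadden:.3f}",
        ])


class ResonanceForest:
    """Bagged classification trees for gesture-level resonance.

    Implemented as bootstrap-aggregated ``DecisionTreeClassifier``s with
    ``max_features=mtry``, which is the classical random forest; the bagging
    wrapper exposes each tree's bootstrap sample so out-of-bag predictions
    are genuine majority votes over the trees that did not see the record.
    Unordered categorical predictors are one-hot encoded; their columns are
    treated as one block for permutation importance and ICE curves.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        predictors: list[str] | None = None,
        outcome: str = "EDA_G_resonance",
        n_trees: int = 1500,
        mtry: int = 3,
        seed: int = 0,
    ):
        self.table = table.reset_index(drop=True)
        self.predictors = list(predictors or DEFAULT_PREDICTORS)
        missing = [c for c in self.predictors + [outcome]
                   if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        self.outcome = outcome
        self.n_trees = int(n_trees)
        self.mtry = int(mtry)
        self.seed = int(seed)
        self.y = self.table[outcome].astype(int).values
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError(f"outcome {outcome!r} must be binary 0/1")
        self._encode()
        self._clf = None

    def _encode(self) -> None:
        blocks: dict[str, list[str]] = {}
        cols = []
        for name in self.predictors:
            col = self.table[name]
            if col.dtype == object or isinstance(
                col.dtype, pd.CategoricalDtype
            ):
                dummies = pd.get_dummies(col.astype(str), prefix=name)
                blocks[name] = list(dummies.columns)
                cols.append(dummies.astype(float))
            else:
                blocks[name] = [name]
                cols.append(col.astype(float).to_frame(name))
        self._X = pd.concat(cols, axis=1)
        self._blocks = blocks
        self._levels = {
            name: sorted(self.table[name].astype(str).unique())
            for name in self.predictors
            if len(self._blocks[name]) > 1
        }

    def fit(self) -> ResonanceForestResults:
        from sklearn.ensemble import BaggingClassifier
        from sklearn.tree import DecisionTreeClassifier

        clf = BaggingClassifier(
            estimator=DecisionTreeClassifier(max_features=self.mtry),
            n_estimators=self.n_trees,
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        )
        X = self._X.values
        clf.fit(X, self.y)
        self._clf = clf
        n = len(self.y)
        self._oob_idx = []
        for sample_idx in clf.estimators_samples_:
            mask = np.ones(n, dtype=bool)
            mask[sample_idx] = False
            self._oob_idx.append(np.nonzero(mask)[0])

        votes1, counts = self._oob_votes(X)
        self._majority_class = int(np.mean(self.y) >= 0.5)
        oob_prob, oob_pred = self._votes_to_pred(votes1, counts)
        n_never = int(np.sum(counts == 0))
        metrics = classification_fit_metrics(self.y, oob_prob, oob_pred)
        return ResonanceForestResults(
            n_trees=self.n_trees, mtry=self.mtry, seed=self.seed,
            outcome=self.outcome, predictors=self.predictors,
            oob_prob=oob_prob, oob_pred=oob_pred,
            oob_accuracy=metrics["accuracy"],
            baseline_rate=metrics["baseline"],
            binom_pvalue=metrics["binom_pvalue"],
            r2_traditional=metrics["r2_traditional"],
            r2_mcfadden=metrics["r2_mcfadden"],
            n_never_oob=n_never, model=self,
        )

    # -- OOB helpers ---------------------------------------------------------

    def _oob_votes(self, X: np.ndarray):
        n = X.shape[0]
        votes1 = np.zeros(n)
        counts = np.zeros(n)
        for tree, oob in zip(self._clf.estimators_, self._oob_idx):
            if oob.size == 0:
                continue
            pred = tree.predict(X[oob])
            votes1[oob] += pred
            counts[oob] += 1
        return votes1, counts

    def _votes_to_pred(self, votes1, counts):
        share = np.divide(votes1, counts,
                          out=np.full_like(votes1, np.mean(self.y)),
                          where=counts > 0)
        pred = np.where(
            share > 0.5, 1,
            np.where(share < 0.5, 0, self._majority_class),
        )
        return share, pred.astype(int)

    def _oob_accuracy_for(self, X: np.ndarray) -> float:
        votes1, counts = self._oob_votes(X)
        _, pred = self._votes_to_pred(votes1, counts)
        return float(np.mean(pred == self.y))

    def _permutation_importance(
        self, results: ResonanceForestResults, n_repeats: int,
        seed: int | None,
    ) -> pd.DataFrame:
        rng = np.random.default_rng(self.seed if seed is None else seed)
        X = self._X.values
        col_pos = {c: i for i, c in enumerate(self._X.columns)}
        rows = []
        for name in self.predictors:
            idx = np.array([col_pos[c] for c in self._blocks[name]])
            drops = []
            for _ in range(n_repeats):
                perm = rng.permutation(len(self.y))
                Xp = X.copy()
                Xp[:, idx] = X[perm][:, idx]
                drops.append(
                    results.oob_accuracy - self._oob_accuracy_for(Xp)
                )
            rows.append({
                "predictor": name,
                "importance": float(np.mean(drops)),
                "se": float(np.std(drops, ddof=1) / np.sqrt(n_repeats))
                if n_repeats > 1 else np.nan,
            })
        out = pd.DataFrame(rows).sort_values(
            "importance", ascending=False
        ).reset_index(drop=True)
        out["rank"] = np.arange(1, len(out) + 1)
        return out

    # -- prediction & ICE ----------------------------------------------------

    def _encode_like(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in self.predictors:
            col = table[name]
            if len(self._blocks[name]) > 1:
                dummies = pd.get_dummies(col.astype(str), prefix=name)
                dummies = dummies.reindex(
                    columns=self._blocks[name], fill_value=0
                )
                cols.append(dummies.astype(float))
            else:
                cols.append(col.astype(float).to_frame(name))
        return pd.concat(cols, axis=1)[self._X.columns].values

    def _predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        X = self._encode_like(table.reset_index(drop=True))
        return self._clf.predict_proba(X)[:, 1]

    def _ice_curves(self, predictor: str, grid, n_grid: int) -> ICECurveSet:
        if predictor not in self.predictors:
            raise ValueError(f"unknown predictor {predictor!r}")
        X = self._X.values
        col_pos = {c: i for i, c in enumerate(self._X.columns)}
        categorical = len(self._blocks[predictor]) > 1
        if grid is None:
            if categorical:
                grid = np.array(self._levels[predictor], dtype=object)
            else:
                col = self._X[self._blocks[predictor][0]].values
                uniq = np.unique(col)
                grid = (uniq if uniq.size <= n_grid
                        else np.linspace(uniq.min(), uniq.max(), n_grid))
        grid = np.asarray(grid)
        curves = np.empty((X.shape[0], grid.size))
        for j, val in enumerate(grid):
            Xg = X.copy()
            if categorical:
                idx = [col_pos[c] for c in self._blocks[predictor]]
                Xg[:, idx] = 0.0
                Xg[:, col_pos[f"{predictor}_{val}"]] = 1.0
            else:
                Xg[:, col_pos[self._blocks[predictor][0]]] = float(val)
            curves[:, j] = self._clf.predict_proba(Xg)[:, 1]
        return ICECurveSet(
            predictor=predictor, grid=grid, values=curves,
            categorical=categorical,
        )


# ---------------------------------------------------------------------------
# convenience entry points


def fit_crescendo(table: pd.DataFrame, **kwargs) -> CrescendoResults:
    """Fit the position -> expressivity crescendo mixed model."""
    return CrescendoModel(table, **kwargs).fit()


def fit_arousal(response_table: pd.DataFrame, **kwargs) -> ArousalResults:
    """Fit the expressivity -> specific-response mixed logistic model."""
    return ArousalModel(response_table, **kwargs).fit()


def fit_resonance_forest(
    table: pd.DataFrame,
    predictors: list[str] | None = None,
    seed: int = 0,
    n_trees: int = 1500,
    mtry: int = 3,
    **kwargs,
) -> ResonanceForestResults:
    """Fit the 13-predictor resonance forest."""
    return ResonanceForest(
        table, predictors=predictors, n_trees=n_trees, mtry=mtry,
        seed=seed, **kwargs
    ).fit()
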