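"""Mixed-effects analysis of proposition recall.

The response is the percentage of propositions recalled per participant
x passage x hierarchy-level cell. Fixed effects are the semantic
hierarchy (detail / mid / main), clarity (vocoded / clear), presentation
format (continuous / self-paced) and passage predictability (low /
high), treatment-coded against the first-listed reference levels.
Random structure: participant and item (passage) intercepts plus an
item-by-hierarchy random slope, fitted by maximum likelihood (not REML)
so that nested models can be compared with likelihood-ratio tests.

Inference follows the reverse-selection workflow: start from a full
model with the two-way interactions, iteratively drop the least
significant non-significant interaction, then test each retained
predictor by comparing the final model to a null model without it —
where the null for a main effect also omits the retained interactions
involving it, which is what gives the semantic hierarchy 4 df (2 for
the main effect + 2 for its retained predictability interaction) and
predictability 3 df (1 + 2).

Marginal effects and hierarchy slopes are computed from unweighted cell
means of the percentages, deliberately model-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .scoring import LEVEL_X

MAIN_EFFECTS = ("hierarchy", "clarity", "format", "predictability")

_TERM_FRAGMENTS = {
    "hierarchy": "C(level, Treatment('detail'))",
    "clarity": "C(clarity, Treatment('vocoded'))",
    "format": "C(format, Treatment('continuous'))",
    "predictability": "C(predictability, Treatment('low'))",
}

#: Contrast names accepted by :func:`marginal_effect`.
CONTRASTS = {
    "predictability": ("predictability", "high", "low"),
    "format": ("format", "selfpaced", "continuous"),
    "clarity": ("clarity", "clear", "vocoded"),
    "hierarchy_main_mid": ("level", "main", "mid"),
    "hierarchy_mid_detail": ("level", "mid", "detail"),
}

DESIGN_FACTORS = ["format", "clarity", "predictability", "level"]


class ConvergenceError(RuntimeError):
    """Mixed-model fit failed to converge even after simplification."""


# bfgs first: on these crossed-design likelihoods lbfgs regularly stops
# short of the optimum (occasionally while still reporting convergence),
# which would inflate likelihood-ratio statistics; bfgs/cg/nm agree on
# the optimum at comparable cost.
_OPTIMIZERS = ("bfgs", "cg", "nm")


def _fit_ml(model, notes: list[str] | None = None):
    """Fit a MixedLM by ML, falling through a chain of optimizers.

    Some optimizers land exactly on a variance-component boundary where
    the Hessian is singular and statsmodels' covariance step fails;
    those attempts are recorded and the next optimizer is tried.
    """
    res = None
    for method in _OPTIMIZERS:
        try:
            res = model.fit(reml=False, method=method, maxiter=500)
        except np.linalg.LinAlgError:
            if notes is not None:
                notes.append(f"optimizer {method} hit a singular Hessian")
            continue
        if res.converged:
            return res
        if notes is not None:
            notes.append(f"optimizer {method} did not converge; trying next")
    return res


def _term_fragment(term: str) -> str:
    if term in _TERM_FRAGMENTS:
        return _TERM_FRAGMENTS[term]
    parts = term.split(":")
    if all(p in _TERM_FRAGMENTS for p in parts):
        return ":".join(_TERM_FRAGMENTS[p] for p in parts)
    raise ValueError(f"unknown model term {term!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect terms plus the (fixed) random structure."""

    terms: tuple[str, ...] = MAIN_EFFECTS
    include_item_slope: bool = True

    def __post_init__(self) -> None:
        for t in self.terms:
            _term_fragment(t)  # validates
        object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def interactions(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if ":" in t)

    def without(self, term: str) -> "ModelSpec":
        if term not in self.terms:
            raise ValueError(f"term {term!r} not in model spec {self.terms}")
        return replace(self, terms=tuple(t for t in self.terms if t != term))

    def without_predictor(self, predictor: str) -> "ModelSpec":
        """Drop a predictor and, for a main effect, its interactions too."""
        if predictor not in self.terms:
            raise ValueError(f"predictor {predictor!r} not in model spec")
        if ":" in predictor:
            return self.without(predictor)
        drop = {
            t for t in self.terms if t == predictor or predictor in t.split(":")
        }
        return replace(self, terms=tuple(t for t in self.terms if t not in drop))

    def formula(self, response: str = "pct") -> str:
        rhs = " + ".join(_term_fragment(t) for t in self.terms) if self.terms else "1"
        return f"{response} ~ {rhs}"


def full_spec(four_way: bool = False) -> ModelSpec:
    """Starting spec for reverse selection: mains + all two-way interactions.

    ``four_way=True`` additionally includes the four-way interaction as
    an optional check.
    """
    pairs = [
        f"{a}:{b}"
        for i, a in enumerate(MAIN_EFFECTS)
        for b in MAIN_EFFECTS[i + 1 :]
    ]
    terms = list(MAIN_EFFECTS) + pairs
    if four_way:
        terms.append(":".join(MAIN_EFFECTS))
    return ModelSpec(tuple(terms))


@dataclass
class FitResult:
    spec: ModelSpec
    llf: float
    n_fixed: int
    converged: bool
    fe_params: pd.Series
    diagnostics: list[str] = field(default_factory=list)
    result: object = None


@dataclass(frozen=True)
class LRTResult:
    predictor: str
    chisq: float
    df: int
    p: float


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    if "proportion" not in df.columns:
        df["proportion"] = df.n_recalled / df.n_props
    df["pct"] = 100.0 * df["proportion"]
    df["level_x"] = df["level"].map(LEVEL_X).astype(float)
    df["_groups"] = 1  # single super-group: crossed effects via vc
    return df


def fit_model(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """ML fit of the mixed model with crossed participant/item effects.

    If the item-by-level random slope prevents convergence it is
    dropped with a warning and the simplification recorded in the
    result diagnostics; outright non-convergence raises.
    """
    df = _prepare(table)
    if df.participant.nunique() < 2 or df.passage.nunique() < 2:
        raise ValueError("need at least 2 participants and 2 items")

    def _try(spec_: ModelSpec) -> tuple[object, list[str]]:
        vc = {"participant": "0 + C(participant)", "item": "0 + C(passage)"}
        if spec_.include_item_slope:
            vc["item_slope"] = "0 + C(passage):level_x"
        notes: list[str] = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = smf.mixedlm(
                spec_.formula(), df, groups="_groups", vc_formula=vc
            )
            res = _fit_ml(model, notes)
        notes.extend(str(w.message) for w in caught)
        if res is None:
            raise ConvergenceError(f"all optimizers failed: {notes}")
        return res, notes

    res, notes = _try(spec)
    used = spec
    if not res.converged and spec.include_item_slope:
        warnings.warn(
            "item-by-level random slope prevented convergence; refitting "
            "with intercepts only",
            stacklevel=2,
        )
        used = replace(spec, include_item_slope=False)
        res, extra = _try(used)
        notes.append("dropped item-by-level random slope (non-convergence)")
        notes.extend(extra)
    if not res.converged:
        raise ConvergenceError(f"mixed model failed to converge: {notes}")
    return FitResult(
        spec=used,
        llf=float(res.llf),
        n_fixed=len(res.fe_params),
        converged=bool(res.converged),
        fe_params=res.fe_params,
        diagnostics=notes,
        result=res,
    )


def lrt(table: pd.DataFrame, final_spec: ModelSpec, predictor: str) -> LRTResult:
    """Likelihood-ratio test of one predictor against the final model.

    The null model omits the predictor; for a main effect it also omits
    the retained interactions involving it (df bookkeeping matching the
    fixed-parameter difference).
    """
    full = fit_model(table, final_spec)
    null_spec = final_spec.without_predictor(predictor)
    null = fit_model(table, null_spec)
    df_diff = full.n_fixed - null.n_fixed
    chisq = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(chisq, df_diff)) if df_diff > 0 else 1.0
    return LRTResult(predictor, chisq, df_diff, p)


@dataclass
class SelectionStep:
    removed: str
    chisq: float
    df: int
    p: float


def reverse_select(
    table: pd.DataFrame, full_spec_: ModelSpec | None = None, alpha: float = 0.05
) -> tuple[ModelSpec, list[SelectionStep]]:
    """Backwards model reduction over interaction terms.

    Repeatedly tests each current interaction with an LRT against the
    current model and removes the least significant one while its p
    exceeds ``alpha``. Main effects are never removed. Returns the
    final spec and the removal log.
    """
    spec = full_spec_ or full_spec()
    log: list[SelectionStep] = []
    while spec.interactions:
        full = fit_model(table, spec)
        tests = []
        for term in spec.interactions:
            # never remove an interaction contained in a retained higher-order one
            if any(
                term != other and set(term.split(":")) < set(other.split(":"))
                for other in spec.interactions
            ):
                continue
            null = fit_model(table, spec.without(term))
            df_diff = full.n_fixed - null.n_fixed
            chisq = max(0.0, 2.0 * (full.llf - null.llf))
            p = float(stats.chi2.sf(chisq, df_diff)) if df_diff > 0 else 1.0
            tests.append(LRTResult(term, chisq, df_diff, p))
        if not tests:
            break
        worst = max(tests, key=lambda t: t.p)
        if worst.p <= alpha:
            break
        spec = spec.without(worst.predictor)
        log.append(SelectionStep(worst.predictor, worst.chisq, worst.df, worst.p))
    return spec, log


def _cell_means(table: pd.DataFrame) -> pd.DataFrame:
    df = _prepare(table)
    return df.groupby(DESIGN_FACTORS, observed=True)["pct"].mean().reset_index()


@dataclass(frozen=True)
class MarginalEffect:
    contrast: str
    estimate: float
    ci: tuple[float, float]


def marginal_effect(
    table: pd.DataFrame,
    factor: str,
    n_boot: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MarginalEffect:
    """Raw marginal contrast in percentage points, with bootstrap CI.

    The estimate is the difference of unweighted cell-mean percentages
    averaged over all other design factors. The CI resamples
    participants with replacement (``n_boot=0`` skips it). Accepted
    factors: "predictability", "format", "clarity",
    "hierarchy_main_mid", "hierarchy_mid_detail".
    """
    if factor not in CONTRASTS:
        raise ValueError(f"unknown factor {factor!r}; one of {sorted(CONTRASTS)}")
    col, hi, lo = CONTRASTS[factor]

    def _estimate(df: pd.DataFrame) -> float:
        cells = _cell_means(df)
        others = [c for c in DESIGN_FACTORS if c != col]
        wide = cells.pivot_table(index=others, columns=col, values="pct", observed=True)
        if wide.isna().any().any():
            warnings.warn(
                f"unbalanced missingness for {factor}; using available cells",
                stacklevel=3,
            )
        return float((wide[hi] - wide[lo]).mean())

    est = _estimate(table)
    if n_boot == 0:
        return MarginalEffect(factor, est, (float("nan"), float("nan")))
    rng = np.random.default_rng(seed)
    participants = table.participant.unique()
    by_part = {p: table[table.participant == p] for p in participants}
    boots = []
    for _ in range(n_boot):
        chosen = rng.choice(participants, size=len(participants), replace=True)
        resampled = pd.concat(
            [by_part[p].assign(participant=f"{p}#{i}") for i, p in enumerate(chosen)],
            ignore_index=True,
        )
        boots.append(_estimate(resampled))
    alpha = 1.0 - ci_level
    ci = (
        float(np.quantile(boots, alpha / 2)),
        float(np.quantile(boots, 1 - alpha / 2)),
    )
    return MarginalEffect(factor, est, ci)


def hierarchy_slope(table: pd.DataFrame, **condition_filter) -> float:
    """Linear hierarchy contrast (main - detail)/2 on cell-mean percentages.

    ``condition_filter`` restricts the cells first, e.g.
    ``hierarchy_slope(t, predictability="low")``. All three levels must
    be present after filtering.
    """
    df = table
    for col, val in condition_filter.items():
        df = df[df[col] == val]
    present = set(df.level.unique())
    if present != {"detail", "mid", "main"}:
        raise ValueError(f"need all three levels after filtering, have {present}")
    means = _prepare(df).groupby("level")["pct"].mean()
    return float((means["main"] - means["detail"]) / 2.0)


# ---------------------------------------------------------------------------
# Pause and covariate analyses


def _recall_pct_by_trial(trials: pd.DataFrame) -> pd.DataFrame:
    """Pooled recall percentage per participant x passage (self-paced only)."""
    sp = trials[trials["format"] == "selfpaced"]
    g = sp.groupby(["participant", "passage"], observed=True)
    out = (100.0 * g.n_recalled.sum() / g.n_props.sum()).rename("pct").reset_index()
    return out


def pause_analyses(trials: pd.DataFrame, pauses: pd.DataFrame) -> dict:
    """Between- and within-participant pause/recall coupling.

    Between: OLS of participant mean self-paced recall percentage on
    participant mean pause duration, reported as an F test with
    (1, n-2) df. Within: mixed model of per-passage recall percentage
    on the person-centered passage mean pause with participant random
    intercepts, tested by a 1-df LRT against the no-pause null.
    """
    if pauses.empty:
        raise ValueError("no pauses provided")
    recall = _recall_pct_by_trial(trials)
    n_participants = recall.participant.nunique()
    if n_participants < 3:
        raise ValueError("need at least 3 participants")

    part_pause = pauses.groupby("participant").pause_s.mean().rename("mean_pause")
    part_recall = recall.groupby("participant").pct.mean().rename("mean_pct")
    between_df = pd.concat([part_pause, part_recall], axis=1).dropna()
    if np.isclose(between_df.mean_pause.var(ddof=0), 0.0):
        raise ValueError("degenerate regressor: pause durations are constant")
    ols = smf.ols("mean_pct ~ mean_pause", between_df).fit()
    between = {
        "F": float(ols.fvalue),
        "df": (1, len(between_df) - 2),
        "p": float(ols.f_pvalue),
        "slope": float(ols.params["mean_pause"]),
    }

    pass_pause = (
        pauses.groupby(["participant", "passage"], observed=True)
        .pause_s.mean()
        .rename("passage_pause")
        .reset_index()
    )
    within_df = recall.merge(pass_pause, on=["participant", "passage"])
    within_df["pause_centered"] = within_df.passage_pause - within_df.groupby(
        "participant"
    ).passage_pause.transform("mean")
    if np.isclose(within_df.pause_centered.var(ddof=0), 0.0):
        raise ValueError("degenerate regressor: no within-participant pause variation")

    def _ml_llf(formula: str) -> tuple[float, int]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _fit_ml(smf.mixedlm(formula, within_df, groups="participant"))
        if res is None:
            raise ConvergenceError(f"pause model failed to converge: {formula}")
        return float(res.llf), len(res.fe_params)

    llf_full, k_full = _ml_llf("pct ~ pause_centered")
    llf_null, k_null = _ml_llf("pct ~ 1")
    chisq = max(0.0, 2.0 * (llf_full - llf_null))
    df_diff = k_full - k_null
    within = LRTResult("passage_pause", chisq, df_diff, float(stats.chi2.sf(chisq, df_diff)))
    return {"between": between, "within": within}


def covariate_predictors(
    table: pd.DataFrame,
    participants: pd.DataFrame,
    final_spec: ModelSpec | None = None,
    covariates: tuple[str, ...] = ("rspan", "vocab", "pta_db"),
) -> dict[str, LRTResult]:
    """LRT for each participant covariate added to the final model.

    ``participants`` must carry columns ``participant`` plus the
    covariates; each is standardized and added as a continuous fixed
    effect, tested with a 1-df LRT against the model without it.
    """
    spec = final_spec or ModelSpec()
    missing = [c for c in covariates if c not in participants.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    merged = table.merge(participants[["participant", *covariates]], on="participant")
    base = fit_model(merged, spec)
    results: dict[str, LRTResult] = {}
    for cov in covariates:
        vals = merged[cov].astype(float)
        if np.isclose(vals.var(ddof=0), 0.0):
            raise ValueError(f"covariate {cov!r} has no variance")
        df = merged.copy()
        df["_zcov"] = (vals - vals.mean()) / vals.std(ddof=0)
        aug = _fit_with_extra(df, spec, "_zcov")
        chisq = max(0.0, 2.0 * (aug.llf - base.llf))
        results[cov] = LRTResult(cov, chisq, 1, float(stats.chi2.sf(chisq, 1)))
    return results


def _fit_with_extra(df: pd.DataFrame, spec: ModelSpec, extra_col: str) -> FitResult:
    """Fit a ModelSpec's model with one extra continuous fixed effect."""
    prepared = _prepare(df)
    vc = {"participant": "0 + C(participant)", "item": "0 + C(passage)"}
    if spec.include_item_slope:
        vc["item_slope"] = "0 + C(passage):level_x"
    formula = spec.formula() + f" + {extra_col}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _fit_ml(smf.mixedlm(formula, prepared, groups="_groups", vc_formula=vc))
    if res is None:
        raise ConvergenceError(f"augmented model failed to converge: {formula}")
    return FitResult(
        spec=spec,
        llf=float(res.llf),
        n_fixed=len(res.fe_params),
        converged=bool(res.converged),
        fe_params=res.fe_params,
        result=res,
    )
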