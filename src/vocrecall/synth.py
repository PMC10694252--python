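"""Synthetic participants, recall outcomes, and self-pacing pauses.

The generator emulates the statistical structure of a 24-participant x
8-passage discourse-recall experiment in a 2 (format) x 2 (clarity) x
2 (predictability) within-subject design with proposition-level recall
scored at three semantic-hierarchy levels.

Generative model (linear-probability, percentage scale)
-------------------------------------------------------
Expected recall percentage for a cell is::

    E[pct] = K + Lc(level) * g(pred)
               + d_pred*[high] + d_format*[selfpaced] + d_clarity*[clear]

where ``Lc`` is the hierarchy contribution (0 / d_mid_detail /
d_mid_detail + d_main_mid for detail / mid / main) centered over the
three levels, and ``g`` rescales the hierarchy slope by predictability:
``g(high) = 2/(1+a)`` and ``g(low) = 2a/(1+a)`` with attenuation
``a = interaction_atten`` (so the mean of ``g`` is 1 and the low/high
slope ratio is exactly ``a``). ``K`` anchors the (detail, low, vocoded,
continuous) cell at ``base_pct``. Centering makes every marginal
contrast of the balanced design equal its calibration delta exactly,
which is what lets a downstream analysis recover the printed effect
sizes as generator parameters.

On top of the fixed part: a participant intercept (correlated with
R-span and with the participant's pause tendency through configurable
loadings), an item intercept, an item-by-level random slope, and an
optional cell-level residual; the observed count is binomial in the
number of propositions at that level.

Pauses are lognormal: ``log pause = mu0 + sig_p*z_i + sig_g*z_ij +
sig_e*eps`` with a participant component (the pause tendency), a
participant-by-passage component shared with that passage's recall
propensity (the within-participant coupling), and a residual, with
``mu0`` moment-matched so the population mean and SD hit their targets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import LEVEL_X, LEVELS
from .stimulus import DesignPlan, Passage, build_design

# Participant covariate populations (means/SDs of the modeled sample).
RSPAN_MEAN, RSPAN_SD, RSPAN_RANGE = 9.42, 2.98, (0, 15)
VOCAB_MEAN, VOCAB_SD, VOCAB_RANGE = 13.00, 1.80, (0, 20)
PTA_MEAN, PTA_SD = 6.88, 4.12


class CalibrationError(ValueError):
    """Raised when a calibration implies cell means outside [0, 100]."""


@dataclass(frozen=True)
class EffectCalibration:
    """Fixed-effect sizes (percentage points) and random-effect SDs.

    The five deltas default to the study's printed marginal effects;
    everything else (baseline, attenuation, SDs, loadings) is not
    derivable from the published summary and defaults to documented
    invented values.
    """

    base_pct: float = 40.0
    d_pred: float = 7.85
    d_main_mid: float = 9.78
    d_mid_detail: float = 5.61
    d_format: float = 6.83
    d_clarity: float = 4.78
    interaction_atten: float = 0.55
    sd_participant: float = 8.0
    sd_item: float = 5.0
    sd_item_slope: float = 2.0
    sd_resid: float = 0.0
    rspan_loading: float = 0.5
    pause_loading_between: float = 0.6
    pause_loading_within: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.interaction_atten <= 1):
            raise CalibrationError("interaction_atten must be in (0, 1]")
        for name in ("sd_participant", "sd_item", "sd_item_slope", "sd_resid"):
            if getattr(self, name) < 0:
                raise CalibrationError(f"{name} must be >= 0")
        load2 = self.rspan_loading**2 + self.pause_loading_between**2
        if load2 > 1:
            raise CalibrationError(
                "rspan_loading^2 + pause_loading_between^2 must be <= 1"
            )
        self.validate_feasible()

    # -- fixed-effect cell means -------------------------------------------

    def _level_contrib(self) -> dict[str, float]:
        return {
            "detail": 0.0,
            "mid": self.d_mid_detail,
            "main": self.d_mid_detail + self.d_main_mid,
        }

    def hierarchy_gain(self, predictability: str) -> float:
        a = self.interaction_atten
        return 2.0 / (1 + a) if predictability == "high" else 2.0 * a / (1 + a)

    def cell_mean(self, level: str, predictability: str, fmt: str, clarity: str) -> float:
        """Expected recall percentage for one design cell (fixed part)."""
        contrib = self._level_contrib()
        centered = {k: v - np.mean(list(contrib.values())) for k, v in contrib.items()}
        anchor = self.base_pct - centered["detail"] * self.hierarchy_gain("low")
        return (
            anchor
            + centered[level] * self.hierarchy_gain(predictability)
            + self.d_pred * (predictability == "high")
            + self.d_format * (fmt == "selfpaced")
            + self.d_clarity * (clarity == "clear")
        )

    def all_cell_means(self) -> pd.DataFrame:
        rows = [
            (lev, pred, fmt, clar, self.cell_mean(lev, pred, fmt, clar))
            for lev in LEVELS
            for pred in ("high", "low")
            for fmt in ("continuous", "selfpaced")
            for clar in ("clear", "vocoded")
        ]
        return pd.DataFrame(
            rows, columns=["level", "predictability", "format", "clarity", "mean_pct"]
        )

    def validate_feasible(self) -> None:
        means = self.all_cell_means()["mean_pct"]
        if (means < 0).any() or (means > 100).any():
            raise CalibrationError(
                f"calibration implies cell means outside [0, 100]: "
                f"range [{means.min():.1f}, {means.max():.1f}]"
            )

    # -- I/O ----------------------------------------------------------------

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EffectCalibration":
        with open(path) as fh:
            return cls(**json.load(fh))

    @classmethod
    def package_default(cls) -> "EffectCalibration":
        """The packaged default calibration."""
        ref = resources.files("vocrecall").joinpath("data/default_calibration.json")
        return cls(**json.loads(ref.read_text()))


@dataclass(frozen=True)
class PauseModel:
    """Lognormal inter-segment pause model, moment-matched.

    ``mean_s``/``sd_s`` are the target population mean and SD of pause
    durations. The total log-scale variance ``ln(1 + (sd/mean)^2)`` is
    split into a participant component (``sigma_participant``, the
    spread of the lognormal pause tendency, unit median), a participant-
    by-passage component (``sigma_passage``), and a residual.
    """

    mean_s: float = 2.43
    sd_s: float = 2.71
    sigma_participant: float = 0.5
    sigma_passage: float = 0.3

    @property
    def sigma_total_sq(self) -> float:
        return float(np.log1p((self.sd_s / self.mean_s) ** 2))

    @property
    def sigma_resid(self) -> float:
        resid_sq = self.sigma_total_sq - self.sigma_participant**2 - self.sigma_passage**2
        if resid_sq <= 0:
            raise CalibrationError(
                "pause variance components exceed the moment-matched total"
            )
        return float(np.sqrt(resid_sq))

    @property
    def mu0(self) -> float:
        """Log-scale location so the population mean equals mean_s."""
        return float(np.log(self.mean_s) - self.sigma_total_sq / 2.0)


#: Propositions per hierarchy level in a typical ~150-word passage.
DEFAULT_N_PROPS = {"main": 10, "mid": 15, "detail": 20}


@dataclass(frozen=True)
class ParticipantProfile:
    id: str
    rspan: int
    vocab: int
    pta_db: float
    pause_tendency: float

    def __post_init__(self) -> None:
        if not (RSPAN_RANGE[0] <= self.rspan <= RSPAN_RANGE[1]):
            raise ValueError(f"rspan out of range: {self.rspan}")
        if not (VOCAB_RANGE[0] <= self.vocab <= VOCAB_RANGE[1]):
            raise ValueError(f"vocab out of range: {self.vocab}")
        if self.pause_tendency <= 0:
            raise ValueError("pause_tendency must be positive")


@dataclass
class SimulatedDataset:
    """Trial-level recall counts, pauses, and the generating truth."""

    trials: pd.DataFrame
    truth: EffectCalibration
    participants: list[ParticipantProfile]
    pauses: pd.DataFrame | None = None
    pause_model: PauseModel = field(default_factory=PauseModel)
    # participant-by-passage pause latents (z-scale), shared between the
    # recall propensity and the pause generator
    pause_latents: pd.DataFrame | None = None

    def cell_table(self) -> pd.DataFrame:
        """Long cell table (adds proportion) for the analysis stage."""
        t = self.trials.copy()
        t["proportion"] = t.n_recalled / t.n_props
        return t


def _rounded_truncnorm(rng, mean, sd, lo, hi, n) -> np.ndarray:
    """Rounded truncated-normal scores whose population mean is ``mean``.

    Truncation shifts the mean of a clipped normal, so the location is
    solved (Brent's method) such that the truncated distribution's mean
    equals the target — the target is the observed sample mean, not the
    latent location.
    """
    from scipy.optimize import brentq

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    loc = brentq(trunc_mean, lo, hi, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    draws = stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)
    return np.clip(np.round(draws), lo, hi).astype(int)


def simulate_participants(
    n: int, seed: int = 0, pause_model: PauseModel | None = None
) -> list[ParticipantProfile]:
    """Draw participant covariate profiles.

    R-span and vocabulary are rounded truncated normals on their score
    ranges; PTA is normal; pause tendency is lognormal with unit median
    and log-scale spread ``pause_model.sigma_participant``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pm = pause_model or PauseModel()
    rng = np.random.default_rng(seed)
    rspan = _rounded_truncnorm(rng, RSPAN_MEAN, RSPAN_SD, *RSPAN_RANGE, n)
    vocab = _rounded_truncnorm(rng, VOCAB_MEAN, VOCAB_SD, *VOCAB_RANGE, n)
    pta = rng.normal(PTA_MEAN, PTA_SD, size=n)
    z_tendency = rng.standard_normal(n)
    tendency = np.exp(pm.sigma_participant * z_tendency)
    return [
        ParticipantProfile(f"P{i:03d}", int(rspan[i]), int(vocab[i]), float(pta[i]), float(tendency[i]))
        for i in range(n)
    ]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def simulate_recall(
    plan: DesignPlan,
    participants: list[ParticipantProfile],
    calibration: EffectCalibration | None = None,
    n_props_per_level: dict[str, int] | None = None,
    seed: int = 0,
    pause_model: PauseModel | None = None,
) -> SimulatedDataset:
    """Simulate proposition-level recall counts for a design plan.

    The participant recall intercept shares a loading with the
    (standardized) R-span score and with the log pause tendency; the
    participant-by-passage pause latent for self-paced passages adds
    ``pause_loading_within * sd_participant`` percentage points per z
    to that passage's recall propensity and is stored on the dataset so
    :func:`simulate_pauses` generates pauses from the same latent.
    """
    cal = calibration or EffectCalibration()
    cal.validate_feasible()
    n_props = dict(DEFAULT_N_PROPS if n_props_per_level is None else n_props_per_level)
    pm = pause_model or PauseModel()
    rng = np.random.default_rng(seed)

    ids = [p.id for p in participants]
    plan_ids = set(plan.table.participant)
    if not plan_ids <= set(ids):
        raise ValueError(f"plan references unknown participants: {plan_ids - set(ids)}")

    z_rspan = _standardize(np.array([p.rspan for p in participants], dtype=float))
    if pm.sigma_participant > 0:
        z_tend = np.array(
            [np.log(p.pause_tendency) / pm.sigma_participant for p in participants]
        )
    else:
        z_tend = np.zeros(len(participants))
    lam_r, lam_b = cal.rspan_loading, cal.pause_loading_between
    resid_load = np.sqrt(max(0.0, 1.0 - lam_r**2 - lam_b**2))
    z_u = lam_r * z_rspan + lam_b * z_tend + resid_load * rng.standard_normal(len(ids))
    u = dict(zip(ids, cal.sd_participant * z_u))

    passages = sorted(plan.table.passage.unique())
    v = dict(zip(passages, cal.sd_item * rng.standard_normal(len(passages))))
    w = dict(zip(passages, cal.sd_item_slope * rng.standard_normal(len(passages))))

    # participant-by-passage pause latents for self-paced trials
    sp = plan.table[plan.table["format"] == "selfpaced"]
    latent_rows = [
        (r.participant, r.passage, rng.standard_normal())
        for r in sp.itertuples()
    ]
    latents = pd.DataFrame(latent_rows, columns=["participant", "passage", "z"])
    latent_map = {(r.participant, r.passage): r.z for r in latents.itertuples()}

    rows = []
    for r in plan.table.itertuples():
        within = 0.0
        if r.format == "selfpaced":
            within = (
                cal.pause_loading_within
                * cal.sd_participant
                * latent_map[(r.participant, r.passage)]
            )
        for lev in LEVELS:
            p_pct = (
                cal.cell_mean(lev, r.predictability, r.format, r.clarity)
                + u[r.participant]
                + v[r.passage]
                + w[r.passage] * LEVEL_X[lev]
                + within
            )
            if cal.sd_resid > 0:
                p_pct += cal.sd_resid * rng.standard_normal()
            p = min(max(p_pct / 100.0, 0.0), 1.0)
            k = int(rng.binomial(n_props[lev], p))
            rows.append(
                (
                    r.participant, r.passage, r.format, r.clarity,
                    r.predictability, lev, n_props[lev], k,
                )
            )
    trials = pd.DataFrame(
        rows,
        columns=[
            "participant", "passage", "format", "clarity", "predictability",
            "level", "n_props", "n_recalled",
        ],
    )
    return SimulatedDataset(
        trials=trials,
        truth=cal,
        participants=list(participants),
        pause_model=pm,
        pause_latents=latents,
    )


def simulate_pauses(
    plan: DesignPlan,
    participants: list[ParticipantProfile],
    recall: SimulatedDataset,
    seed: int = 0,
    n_segments_per_passage: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Generate inter-segment pause durations for self-paced trials.

    One pause per segment transition (n_segments - 1 per passage).
    ``log pause = mu0 + sigma_p*z_i + sigma_g*z_ij + sigma_e*eps`` with
    the participant z from the profile's pause tendency and the
    participant-by-passage z shared with the recall propensity; clarity
    has no effect on pauses.
    """
    pm = recall.pause_model
    sp = plan.table[plan.table["format"] == "selfpaced"]
    if sp.empty:
        raise ValueError("plan contains no self-paced trials")
    if n_segments_per_passage is None:
        passages = sorted(plan.table.passage.unique())
        # ~10.5 segments per passage: alternate 10 and 11
        n_segments_per_passage = {
            pid: 10 + (i % 2) for i, pid in enumerate(passages)
        }
    tendency = {p.id: p.pause_tendency for p in participants}
    latent_map = {
        (r.participant, r.passage): r.z for r in recall.pause_latents.itertuples()
    }
    rng = np.random.default_rng(seed)
    sigma_e = pm.sigma_resid
    rows = []
    for r in sp.itertuples():
        n_pauses = n_segments_per_passage[r.passage] - 1
        log_base = (
            pm.mu0
            + np.log(tendency[r.participant])
            + pm.sigma_passage * latent_map[(r.participant, r.passage)]
        )
        pauses = np.exp(log_base + sigma_e * rng.standard_normal(n_pauses))
        rows.extend(
            (r.participant, r.passage, k, float(pauses[k])) for k in range(n_pauses)
        )
    return pd.DataFrame(rows, columns=["participant", "passage", "segment_index", "pause_s"])


def simulate_dataset(
    n_participants: int = 24,
    seed: int = 0,
    calibration: EffectCalibration | None = None,
    n_props_per_level: dict[str, int] | None = None,
    pause_model: PauseModel | None = None,
) -> SimulatedDataset:
    """End-to-end convenience: passages, design, participants, recall, pauses.

    Sub-stage seeds are spawned deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_design, s_part, s_recall, s_pause = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    passages = make_synthetic_passages()
    plan = build_design(n_participants, passages, s_design)
    pm = pause_model or PauseModel()
    participants = simulate_participants(n_participants, s_part, pm)
    ds = simulate_recall(
        plan, participants, calibration, n_props_per_level, s_recall, pm
    )
    ds.pauses = simulate_pauses(plan, participants, ds, s_pause)
    return ds


def make_synthetic_passages() -> list[Passage]:
    """Eight synthetic passages mirroring the study's stimulus geometry.

    Four high-predictability (mean cloze 0.67) and four low (0.51)
    passages of ~80 placeholder words; real passage text is not needed
    for design building or simulation. Synthetic stand-ins, not the
    study's copyrighted materials.
    """
    passages = []
    for i in range(4):
        for cls, cloze in (("high", 0.67), ("low", 0.51)):
            pid = f"{cls[0].upper()}{i + 1}"
            words = tuple(f"{pid.lower()}w{k:03d}" for k in range(80))
            passages.append(Passage(pid, words, cls, cloze))
    return passages
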