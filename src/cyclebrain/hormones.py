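"""Synthetic endocrine profiles across the menstrual cycle.

Generates daily serum estradiol (pmol/l) and progesterone (nmol/l) series for
five profile templates — two typical ovulatory cycles, a short
estradiol-dominant endometriosis cycle, an oral-contraceptive (OC) cycle with
selectively suppressed progesterone, and a male control with low, weakly
fluctuating levels — together with the hormone transforms used by every
downstream stage (square root, z-standardization, progesterone-to-estradiol
ratio).

The deterministic part of each female trajectory is a sum of Gaussian bumps
over a baseline: a pre-ovulatory estradiol peak, a mid-luteal progesterone
bump, and a smaller mid-luteal secondary estradiol bump.  Multiplicative
lognormal noise with a configurable coefficient of variation models day-to-day
assay and physiological variability.  The progesterone-to-estradiol ratio is
computed with both hormones expressed in pmol/l, i.e. ``R = 1000 * P / E``
with P in nmol/l and E in pmol/l.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HormoneProfileConfig",
    "HormoneSeries",
    "TEMPLATES",
    "simulate_cycle",
    "classify_ovulatory",
    "sqrt_transform",
    "standardize",
    "write_hormone_tsv",
    "read_hormone_tsv",
]

#: Serum progesterone above this level indicates that ovulation occurred
#: (strict inequality).  Units: nmol/l.
OVULATION_P_THRESHOLD = 15.9

_PHASES = ("menses", "follicular", "ovulation", "luteal", "inactive_pill")


@dataclass(frozen=True)
class HormoneProfileConfig:
    """Parameters of one endocrine profile template.

    Concentrations are serum levels: estradiol in pmol/l, progesterone in
    nmol/l.  ``noise_cv`` is the coefficient of variation of the
    multiplicative lognormal day-to-day noise.
    """

    template: str
    cycle_length_days: int
    ovulation_day: int | None
    estradiol_peak: float
    progesterone_luteal_peak: float
    baseline_estradiol: float
    baseline_progesterone: float
    noise_cv: float
    seed: int = 0
    luteal_length_days: int = 14
    #: secondary (luteal) estradiol bump height as a fraction of the
    #: follicular peak height above baseline
    luteal_estradiol_frac: float = 0.45
    #: clip simulated values to an observed range, e.g. for the male template
    estradiol_range: tuple[float, float] | None = None
    progesterone_range: tuple[float, float] | None = None
    #: override noise CV for progesterone (None -> use noise_cv); lets the
    #: male template carry the much larger relative progesterone variability
    progesterone_noise_cv: float | None = None
    #: "pmol_per_pmol" (default): R = 1000*P/E; "nmol_per_pmol": R = P/E
    ratio_convention: str = "pmol_per_pmol"

    def __post_init__(self) -> None:
        if self.template != "male" and not 20 <= self.cycle_length_days <= 35:
            raise ValueError(
                f"cycle_length_days must be in [20, 35], got {self.cycle_length_days}"
            )
        if self.template == "male" and self.ovulation_day is not None:
            raise ValueError("male template must have ovulation_day=None")
        for name in (
            "estradiol_peak",
            "progesterone_luteal_peak",
            "baseline_estradiol",
            "baseline_progesterone",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.template == "oc" and (
            self.progesterone_luteal_peak > self.baseline_progesterone
        ):
            raise ValueError(
                "oc template requires suppressed progesterone "
                "(luteal peak <= baseline)"
            )


def _template_defaults(template: str, seed: int) -> HormoneProfileConfig:
    common = dict(template=template, seed=seed)
    if template == "typical":
        # 27-day cycle, 14-day luteal phase -> ovulation on day 13
        return HormoneProfileConfig(
            cycle_length_days=27, ovulation_day=13,
            estradiol_peak=750.0, progesterone_luteal_peak=35.0,
            baseline_estradiol=150.0, baseline_progesterone=1.5,
            noise_cv=0.12, luteal_length_days=14, **common,
        )
    if template == "typical_28andme":
        # daily sampling, 14 follicular + 16 luteal days covered
        return HormoneProfileConfig(
            cycle_length_days=30, ovulation_day=14,
            estradiol_peak=700.0, progesterone_luteal_peak=40.0,
            baseline_estradiol=140.0, baseline_progesterone=1.2,
            noise_cv=0.12, luteal_length_days=16, **common,
        )
    if template == "endometriosis":
        # short (<=24 d) cycle, 8-day luteal phase, estradiol-dominant
        return HormoneProfileConfig(
            cycle_length_days=24, ovulation_day=16,
            estradiol_peak=850.0, progesterone_luteal_peak=20.0,
            baseline_estradiol=280.0, baseline_progesterone=1.5,
            noise_cv=0.12, luteal_length_days=8, luteal_estradiol_frac=0.75,
            **common,
        )
    if template == "oc":
        # combined pill: progesterone selectively suppressed, estradiol
        # level and dynamic range comparable to a natural cycle
        return HormoneProfileConfig(
            cycle_length_days=28, ovulation_day=None,
            estradiol_peak=400.0, progesterone_luteal_peak=1.0,
            baseline_estradiol=180.0, baseline_progesterone=1.0,
            noise_cv=0.15, **common,
        )
    if template == "male":
        # calibrated to the observed male summary statistics
        return HormoneProfileConfig(
            cycle_length_days=35, ovulation_day=None,
            estradiol_peak=129.0, progesterone_luteal_peak=0.863,
            baseline_estradiol=128.7, baseline_progesterone=0.863,
            noise_cv=0.13, progesterone_noise_cv=0.62,
            estradiol_range=(98.0, 161.0),
            progesterone_range=(0.329, 3.420),
            **common,
        )
    raise ValueError(f"unknown template {template!r}")


class _Templates:
    """Mapping-style accessor for the built-in profile templates."""

    names = ("typical", "typical_28andme", "endometriosis", "oc", "male")

    def __call__(self, template: str, seed: int = 0) -> HormoneProfileConfig:
        return _template_defaults(template, seed)

    def __iter__(self):
        return iter(self.names)


TEMPLATES = _Templates()


@dataclass
class HormoneSeries:
    """One individual's hormone trajectory over the sampled test days."""

    individual_id: str
    day: np.ndarray            # 1-based test-day index, strictly increasing
    estradiol: np.ndarray      # pmol/l
    progesterone: np.ndarray   # nmol/l
    ratio: np.ndarray          # unitless, pmol/pmol convention
    phase: np.ndarray          # strings from _PHASES

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=int)
        self.estradiol = np.asarray(self.estradiol, dtype=float)
        self.progesterone = np.asarray(self.progesterone, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if len(self.day) == 0:
            raise ValueError("empty hormone series")
        if np.any(np.diff(self.day) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.estradiol <= 0) or np.any(self.progesterone <= 0):
            raise ValueError("hormone concentrations must be positive")
        unknown = set(self.phase) - set(_PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.day)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "day": self.day,
                "estradiol_pmol_l": self.estradiol,
                "progesterone_nmol_l": self.progesterone,
                "ratio": self.ratio,
                "phase": self.phase,
            }
        )


def compute_ratio(
    progesterone_nmol_l: np.ndarray,
    estradiol_pmol_l: np.ndarray,
    convention: str = "pmol_per_pmol",
) -> np.ndarray:
    """Progesterone-to-estradiol ratio.

    With the default convention both hormones are expressed in pmol/l before
    division (progesterone is converted by a factor 1000).
    """
    p = np.asarray(progesterone_nmol_l, dtype=float)
    e = np.asarray(estradiol_pmol_l, dtype=float)
    if convention == "pmol_per_pmol":
        return 1000.0 * p / e
    if convention == "nmol_per_pmol":
        return p / e
    raise ValueError(f"unknown ratio convention {convention!r}")


def _phase_labels(config: HormoneProfileConfig, cycle_day: np.ndarray) -> np.ndarray:
    labels = np.empty(len(cycle_day), dtype=object)
    if config.template == "male":
        labels[:] = "follicular"  # no cyclic phases; neutral label
        return labels
    if config.template == "oc":
        labels[:] = "follicular"
        labels[cycle_day <= 5] = "menses"
        labels[cycle_day > config.cycle_length_days - 7] = "inactive_pill"
        return labels
    ov = config.ovulation_day
    labels[:] = "follicular"
    labels[cycle_day <= 5] = "menses"
    labels[cycle_day == ov] = "ovulation"
    labels[cycle_day > ov] = "luteal"
    return labels


def _mean_curves(
    config: HormoneProfileConfig, cycle_day: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free estradiol/progesterone mean trajectories."""
    d = cycle_day.astype(float)
    e = np.full_like(d, config.baseline_estradiol)
    p = np.full_like(d, config.baseline_progesterone)
    if config.ovulation_day is not None:
        ov = float(config.ovulation_day)
        mid_luteal = ov + config.luteal_length_days / 2.0
        e_amp = config.estradiol_peak - config.baseline_estradiol
        # pre-ovulatory estradiol surge peaks the day before ovulation
        e += e_amp * np.exp(-0.5 * ((d - (ov - 1.0)) / 1.8) ** 2)
        # secondary luteal estradiol bump
        e += (
            config.luteal_estradiol_frac
            * e_amp
            * np.exp(-0.5 * ((d - mid_luteal) / (config.luteal_length_days / 3.5)) ** 2)
        )
        p_amp = config.progesterone_luteal_peak - config.baseline_progesterone
        p += p_amp * np.exp(
            -0.5 * ((d - mid_luteal) / (config.luteal_length_days / 3.0)) ** 2
        )
    elif config.template == "oc":
        # mild slow estradiol modulation mimicking a natural dynamic range
        e *= 1.0 + 0.35 * np.sin(2.0 * np.pi * d / config.cycle_length_days)
    return e, p


def simulate_cycle(
    config: HormoneProfileConfig, session_days: Sequence[int]
) -> HormoneSeries:
    """Simulate a hormone series at the given test days.

    Deterministic given ``config.seed``.  Days beyond ``cycle_length_days``
    wrap into the next cycle (sampling windows may span two cycles).
    """
    days = np.asarray(session_days, dtype=int)
    if days.size == 0:
        raise ValueError("session_days is empty")
    if np.any(np.diff(days) <= 0):
        raise ValueError("session_days must be strictly increasing")

    cycle_day = ((days - 1) % config.cycle_length_days) + 1
    e_mean, p_mean = _mean_curves(config, cycle_day)

    rng = np.random.default_rng(config.seed)
    p_cv = (
        config.noise_cv
        if config.progesterone_noise_cv is None
        else config.progesterone_noise_cv
    )

    def _lognoise(mean, cv):
        if cv <= 0:
            return mean.copy()
        sigma = float(np.sqrt(np.log1p(cv**2)))
        return mean * np.exp(
            sigma * rng.standard_normal(days.size) - 0.5 * sigma**2
        )

    e = _lognoise(e_mean, config.noise_cv)
    p = _lognoise(p_mean, p_cv)

    if config.estradiol_range is not None:
        e = np.clip(e, *config.estradiol_range)
    if config.progesterone_range is not None:
        p = np.clip(p, *config.progesterone_range)

    return HormoneSeries(
        individual_id=config.template,
        day=days,
        estradiol=e,
        progesterone=p,
        ratio=compute_ratio(p, e, config.ratio_convention),
        phase=_phase_labels(config, cycle_day),
    )


def classify_ovulatory(series: HormoneSeries) -> bool:
    """True iff peak progesterone strictly exceeds 15.9 nmol/l."""
    return bool(np.max(series.progesterone) > OVULATION_P_THRESHOLD)


def sqrt_transform(values: Sequence[float]) -> np.ndarray:
    """Element-wise square root (variance-stabilizing hormone transform)."""
    v = np.asarray(values, dtype=float)
    neg = np.flatnonzero(v < 0)
    if neg.size:
        raise ValueError(
            f"negative value at index {int(neg[0])}: {v[neg[0]]!r}"
        )
    return np.sqrt(v)


def standardize(values: Sequence[float]) -> np.ndarray:
    """Z-score with the sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


# ---------------------------------------------------------------------------
# TSV interface

_TSV_COLUMNS = [
    "individual_id",
    "day",
    "estradiol_pmol_l",
    "progesterone_nmol_l",
    "ratio",
    "phase",
]


def write_hormone_tsv(series_list: Sequence[HormoneSeries], path) -> None:
    frame = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_hormone_tsv(path) -> list[HormoneSeries]:
    """Read a hormone table; a missing ratio column is recomputed."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"individual_id", "day", "estradiol_pmol_l", "progesterone_nmol_l"} - set(
        frame.columns
    )
    if missing:
        raise ValueError(f"hormone table missing columns: {sorted(missing)}")
    if "ratio" not in frame.columns:
        frame["ratio"] = compute_ratio(
            frame["progesterone_nmol_l"].to_numpy(),
            frame["estradiol_pmol_l"].to_numpy(),
        )
    if "phase" not in frame.columns:
        frame["phase"] = "follicular"
    out = []
    for ind, grp in frame.groupby("individual_id", sort=False):
        grp = grp.sort_values("day")
        out.append(
            HormoneSeries(
                individual_id=str(ind),
                day=grp["day"].to_numpy(),
                estradiol=grp["estradiol_pmol_l"].to_numpy(),
                progesterone=grp["progesterone_nmol_l"].to_numpy(),
                ratio=grp["ratio"].to_numpy(),
                phase=grp["phase"].to_numpy(dtype=object),
            )
        )
    return out
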