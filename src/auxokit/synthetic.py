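"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators, one per downstream stage:

* plate-reader growth curves in the semi-continuous depletion design
  (exponential growth, storage-limited arrest, dilution after every two
  doublings, multiplicative log-scale noise, a detector linear range);
* binary COG presence/absence matrices in which designated marker COGs are
  depleted in auxotrophs with configurable penetrance over a background of
  random pathway gaps;
* strain growth-parameter tables in which auxotrophs draw stochastically
  lower rates and yields than prototrophs.

Every generator is deterministic under its ``seed``; plate curves use one
RNG stream per (seed, strain, replicate) so adding replicates never perturbs
existing ones, and the depleted and control arm of a replicate replay the
same stream (paired-well noise).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genomics import CogPresenceMatrix
from .growth import LN2, ODTimeSeries

__all__ = [
    "CurveSpec",
    "GenomeSpec",
    "CommunitySpec",
    "simulate_plate_growth",
    "simulate_cog_matrix",
    "simulate_strain_params",
]


@dataclass
class CurveSpec:
    """Parameters of one strain's depletion experiment.

    ``storage_doublings`` maps each vitamin to the number of doublings the
    strain can perform after that vitamin is withdrawn; ``math.inf`` marks a
    prototroph for the vitamin. ``od_dilution_trigger`` is the doubling count
    between transfers to fresh medium (2 in the semi-continuous design).
    ``arrest_rate`` is the growth rate after storage exhaustion (0 = full
    stop); ``arrest_ramp_h`` optionally ramps the rate down linearly over
    that many hours instead of instantaneously.
    """

    strain_id: str = "strain"
    mu_max: float = 0.6  # per hour
    od0: float = 0.05
    storage_doublings: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.02  # sd of log-scale multiplicative OD noise
    sample_interval_h: float = 1.0 / 6.0  # 10-minute readings
    od_dilution_trigger: float = 2.0
    linear_range: tuple[float, float] = (0.01, 1.0)
    n_replicates: int = 3
    duration_h: float = 12.0
    seed: int = 0
    arrest_rate: float = 0.0
    arrest_ramp_h: float = 0.0
    noise_model: str = "lognormal"  # or "additive"

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        lo, hi = self.linear_range
        if not (lo < hi):
            raise ValueError("linear_range must be ordered (lo, hi)")
        if not (lo <= self.od0 <= hi):
            raise ValueError("od0 must lie within linear_range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(v < 0 for v in self.storage_doublings.values()):
            raise ValueError("storage_doublings must be non-negative")
        if self.sample_interval_h <= 0:
            raise ValueError("sample_interval_h must be positive")
        if self.od_dilution_trigger <= 0:
            raise ValueError("od_dilution_trigger must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.arrest_rate < 0 or self.arrest_ramp_h < 0:
            raise ValueError("arrest parameters must be non-negative")
        if self.noise_model not in ("lognormal", "additive"):
            raise ValueError("noise_model must be 'lognormal' or 'additive'")


@dataclass
class GenomeSpec:
    """Parameters of a synthetic COG presence/absence matrix.

    Marker COGs (per vitamin) are absent in auxotrophs with probability
    ``marker_absence_rate_aux`` and present in prototrophs with probability
    ``marker_presence_rate_proto``; every other (background) COG is i.i.d.
    Bernoulli(``background_presence_rate``) in all strains, emulating the
    random biosynthetic-pathway gaps seen in all strains regardless of
    phenotype.
    """

    n_auxotrophs: int = 18
    n_prototrophs: int = 17
    marker_cogs: Mapping[str, list[str]] = field(default_factory=dict)
    marker_absence_rate_aux: float = 1.0
    marker_presence_rate_proto: float = 0.76
    background_cogs: int = 100
    background_presence_rate: float = 0.6
    pathway_map: dict[str, str] = field(default_factory=dict)
    n_background_pathways: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (
            self.marker_absence_rate_aux,
            self.marker_presence_rate_proto,
            self.background_presence_rate,
        ):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if self.n_auxotrophs < 0 or self.n_prototrophs < 0 or self.background_cogs < 0:
            raise ValueError("counts must be non-negative")
        for vit, cogs in self.marker_cogs.items():
            for cog in cogs:
                if cog not in self.pathway_map:
                    raise ValueError(f"marker COG {cog!r} missing from pathway_map")


@dataclass
class CommunitySpec:
    """Parameters of a synthetic 20-strain co-culture community.

    Default ranges put every prototroph and about half the auxotrophs above
    the 0.3 1/h by-product secretion threshold (expected 15 of 20 strains)
    and about a quarter of prototrophs above 0.6 1/h (expected 3 of 20),
    with auxotrophs drawing lower rates and yields than prototrophs.
    """

    n_strains: int = 20
    aux_fraction: float = 0.5
    mu_range_aux: tuple[float, float] = (0.15, 0.45)
    mu_range_proto: tuple[float, float] = (0.30, 0.70)
    yield_range_aux: tuple[float, float] = (0.3, 0.7)
    yield_range_proto: tuple[float, float] = (0.6, 1.2)
    cfu_per_od_range: tuple[float, float] = (5e8, 2e9)
    stationary_scatter: tuple[float, float] = (0.9, 1.1)
    spacing: str = "random"  # or "quantile" for a fixed calibrated community
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing not in ("random", "quantile"):
            raise ValueError("spacing must be 'random' or 'quantile'")
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if not (0 <= self.aux_fraction <= 1):
            raise ValueError("aux_fraction must lie in [0, 1]")
        for rng in (
            self.mu_range_aux,
            self.mu_range_proto,
            self.yield_range_aux,
            self.yield_range_proto,
            self.cfu_per_od_range,
            self.stationary_scatter,
        ):
            lo, hi = rng
            if not (0 < lo <= hi):
                raise ValueError(f"range must be positive and ordered, got {rng}")


def _replicate_rng(seed: int, strain_id: str, replicate: int) -> np.random.Generator:
    # crc32 keeps the stream stable across interpreter runs (unlike hash()).
    ss = np.random.SeedSequence([seed, zlib.crc32(strain_id.encode()), replicate])
    return np.random.default_rng(ss)


class _GrowthModel:
    """Closed-form doublings-vs-time curve with arrest and its inverse."""

    def __init__(self, spec: CurveSpec, storage: float) -> None:
        self.mu = spec.mu_max
        self.arrest = spec.arrest_rate
        self.ramp = spec.arrest_ramp_h
        self.storage = storage
        self.t_star = math.inf if math.isinf(storage) else storage * LN2 / self.mu

    def doublings(self, t: float) -> float:
        if t <= self.t_star:
            return self.mu * t / LN2
        d = self.storage
        dt = t - self.t_star
        if self.ramp > 0:
            ramp_dt = min(dt, self.ramp)
            # rate interpolates mu -> arrest linearly over the ramp
            d += (self.mu * ramp_dt - (self.mu - self.arrest) * ramp_dt**2 / (2 * self.ramp)) / LN2
            dt -= ramp_dt
        return d + self.arrest * dt / LN2

    def time_at(self, d: float) -> float | None:
        """Earliest time reaching d cumulative doublings (None if never)."""
        if d <= self.storage or math.isinf(self.t_star):
            return d * LN2 / self.mu
        extra = (d - self.storage) * LN2  # in ln-units past arrest onset
        if self.ramp > 0:
            ramp_total = self.mu * self.ramp - (self.mu - self.arrest) * self.ramp / 2
            if extra <= ramp_total:
                a = -(self.mu - self.arrest) / (2 * self.ramp)
                disc = self.mu**2 + 4 * a * extra
                if disc < 0:
                    return None
                return self.t_star + (-self.mu + math.sqrt(disc)) / (2 * a)
            extra -= ramp_total
            base = self.t_star + self.ramp
        else:
            base = self.t_star
        if self.arrest <= 0:
            return None
        return base + extra / self.arrest


def _generate_series(
    spec: CurveSpec,
    storage: float,
    condition: str,
    rng: np.random.Generator,
    replicate: int,
) -> ODTimeSeries:
    model = _GrowthModel(spec, storage)
    n = int(math.floor(spec.duration_h / spec.sample_interval_h)) + 1
    times = np.arange(n) * spec.sample_interval_h

    # dilution times: cumulative doublings crossing successive multiples of
    # the trigger; OD resets exactly to od0, so the factor is 2**trigger
    events: list[tuple[float, float]] = []
    k = 1
    while True:
        te = model.time_at(k * spec.od_dilution_trigger)
        if te is None or te > spec.duration_h:
            break
        events.append((float(te), float(2.0**spec.od_dilution_trigger)))
        k += 1

    d = np.array([model.doublings(t) for t in times])
    n_dil = np.array([sum(1 for te, _ in events if te <= t) for t in times])
    od_true = spec.od0 * 2.0 ** (d - n_dil * spec.od_dilution_trigger)

    noise = rng.normal(0.0, 1.0, size=n)
    if spec.noise_sd == 0:
        od = od_true.copy()
    elif spec.noise_model == "lognormal":
        od = od_true * np.exp(spec.noise_sd * noise)
    else:
        od = od_true + spec.noise_sd * noise

    lo, hi = spec.linear_range
    flags = np.full(n, "", dtype=object)
    flags[od <= 0] = "nonpositive"
    below = (od > 0) & (od < lo)
    above = od > hi
    od = np.clip(od, None, hi)
    od[below] = lo
    flags[below] = "below_range"
    flags[above] = "above_range"

    return ODTimeSeries(
        time_h=times,
        od=od,
        strain=spec.strain_id,
        replicate=str(replicate + 1),
        condition=condition,
        dilution_events=events,
        flags=flags,
    )


def simulate_plate_growth(
    spec: CurveSpec, vitamin: str | None = None
) -> tuple[list[ODTimeSeries], list[ODTimeSeries]]:
    """Generate paired (control, depleted) replicate curves for one strain.

    The supplemented control grows exponentially at ``mu_max`` throughout;
    the depleted arm grows identically until cumulative doublings reach
    ``storage_doublings[vitamin]``, then the rate drops to ``arrest_rate``.
    Returns ``(controls, depleted)``; ``depleted`` is empty when ``vitamin``
    is None. Each replicate's two arms share one noise stream, so a
    prototroph (storage = inf) yields byte-identical pairs.
    """
    if vitamin is not None and vitamin not in spec.storage_doublings:
        raise KeyError(f"unknown vitamin {vitamin!r}; spec defines {sorted(spec.storage_doublings)}")
    controls: list[ODTimeSeries] = []
    depleted: list[ODTimeSeries] = []
    for r in range(spec.n_replicates):
        controls.append(
            _generate_series(spec, math.inf, "supplemented", _replicate_rng(spec.seed, spec.strain_id, r), r)
        )
        if vitamin is not None:
            depleted.append(
                _generate_series(
                    spec,
                    float(spec.storage_doublings[vitamin]),
                    f"depleted:{vitamin}",
                    _replicate_rng(spec.seed, spec.strain_id, r),
                    r,
                )
            )
    return controls, depleted


def simulate_cog_matrix(spec: GenomeSpec) -> CogPresenceMatrix:
    """Generate a labelled binary COG matrix over auxotrophs and prototrophs.

    Marker COGs are drawn per strain with class-specific Bernoulli rates;
    background COGs are i.i.d. Bernoulli in all strains and assigned
    round-robin to synthetic background pathways so they survive the
    pathway-mapped restriction of the association stage. Every auxotroph is
    labelled auxotrophic for every vitamin in ``marker_cogs``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC06]))
    aux = [f"aux_{i+1:03d}" for i in range(spec.n_auxotrophs)]
    proto = [f"proto_{i+1:03d}" for i in range(spec.n_prototrophs)]
    strains = aux + proto
    if not strains:
        raise ValueError("need at least one strain")

    pathway_map = dict(spec.pathway_map)
    cols: dict[str, np.ndarray] = {}
    for vit in sorted(spec.marker_cogs):
        for cog in spec.marker_cogs[vit]:
            pa = rng.random(len(aux)) >= spec.marker_absence_rate_aux
            pp = rng.random(len(proto)) < spec.marker_presence_rate_proto
            cols[cog] = np.concatenate([pa, pp])
    for b in range(spec.background_cogs):
        cog = f"BG{b+1:04d}"
        cols[cog] = rng.random(len(strains)) < spec.background_presence_rate
        pathway_map.setdefault(cog, f"background_pathway_{b % spec.n_background_pathways + 1}")

    presence = pd.DataFrame(cols, index=strains, dtype=bool)
    vitamins = sorted(spec.marker_cogs) or ["none"]
    labels = pd.DataFrame(
        {v: ["auxotroph"] * len(aux) + ["prototroph"] * len(proto) for v in vitamins},
        index=strains,
    )
    return CogPresenceMatrix(presence=presence, pathway_map=pathway_map, labels=labels)


def simulate_strain_params(spec: CommunitySpec) -> pd.DataFrame:
    """Generate a strain growth-parameter table for the community models.

    Columns: strain_id, mu_max, yield_od, cfu_per_od, stationary_cfu_ml,
    is_auxotroph. Rates and yields are uniform draws from the class-specific
    range; carrying capacity, substrate affinity and initial abundance are
    derived downstream by :func:`auxokit.crm.derive_params`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC12]))
    n_aux = int(round(spec.n_strains * spec.aux_fraction))
    n_proto = spec.n_strains - n_aux
    is_aux = np.array([True] * n_aux + [False] * n_proto)
    if spec.spacing == "quantile":
        # evenly spaced class quantiles emulate one fixed, experimentally
        # characterized community (e.g. exactly 15 of 20 strains at or above
        # the 0.3/h secretion threshold under the default ranges); rate/yield
        # pairing and the remaining columns stay seed-dependent
        def spaced(lo_hi: tuple[float, float], n: int) -> np.ndarray:
            return np.linspace(lo_hi[0], lo_hi[1], n) if n > 1 else np.array([np.mean(lo_hi)])

        mu = np.concatenate(
            [spaced(spec.mu_range_aux, n_aux), spaced(spec.mu_range_proto, n_proto)]
        )
        yld = np.concatenate(
            [
                rng.permutation(spaced(spec.yield_range_aux, n_aux)),
                rng.permutation(spaced(spec.yield_range_proto, n_proto)),
            ]
        )
    else:
        mu = np.where(
            is_aux,
            rng.uniform(*spec.mu_range_aux, size=spec.n_strains),
            rng.uniform(*spec.mu_range_proto, size=spec.n_strains),
        )
        yld = np.where(
            is_aux,
            rng.uniform(*spec.yield_range_aux, size=spec.n_strains),
            rng.uniform(*spec.yield_range_proto, size=spec.n_strains),
        )
    cfu_per_od = rng.uniform(*spec.cfu_per_od_range, size=spec.n_strains)
    # stationary density in batch monoculture is the carrying capacity up to
    # measurement scatter, so it is tied to yield x CFU/OD rather than drawn
    # independently
    stationary = yld * cfu_per_od * rng.uniform(*spec.stationary_scatter, size=spec.n_strains)
    return pd.DataFrame(
        {
            "strain_id": [
                f"aux_{i+1:02d}" if a else f"proto_{i-n_aux+1:02d}"
                for i, a in enumerate(is_aux)
            ],
            "mu_max": mu,
            "yield_od": yld,
            "cfu_per_od": cfu_per_od,
            "stationary_cfu_ml": stationary,
            "is_auxotroph": is_aux,
        }
    )
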