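"""Consumer-resource models of the 20-strain co-culture experiment.

The default model couples per-strain Monod-limited logistic growth on a
single shared glucose pool to a serial-dilution schedule:

    mu_i   = mu_max_i * S / (S + K_i)
    dN_i/dt = mu_i * N_i * (1 - N_i / C_i)
    dS/dt   = -sum_i (10 * mu_i * N_i / C_i) * S

with [Glucose](0) = 20 mM and, at t in {24, 48, 72, 96} h, N_i -> N_i/200
and S -> 20 (transfer into fresh medium). The carrying capacity C_i is the
experimentally determined yield (OD) times the CFU count per OD unit; the
substrate affinity K_i is the maximum yield over all strains divided by the
strain's own yield (a dimensionless ratio used directly in the mM slot — a
unit shortcut inherited from the model's construction); the flux coefficient
10 converts a realized growth rate into a glucose consumption rate.

Two extensions: (1) vitamin cross-feeding replaces carrying capacities with
their high-vitamin (10 uM) values, imputing missing strains with the mean
fold-increase; (2) carbon cross-feeding lets fast growers (mu_max >= 0.3/h)
secrete a second carbon source S2 at 50% of their glucose consumption flux,
on which only the slow growers (mu_max below the threshold) can grow with an
efficiency scaling factor (1/3, or 1 for preferentially feeding auxotrophs).

Species richness is the number of detected strains (relative abundance at or
above a presence threshold, default 0.5% of total) divided by the number
introduced, reported separately for auxotrophs and prototrophs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "CRMConfig",
    "Trajectory",
    "RichnessSeries",
    "derive_params",
    "monod_rate",
    "simulate_default",
    "simulate_vitamin_xfeed",
    "simulate_carbon_xfeed",
    "species_richness",
    "sensitivity_bands",
]


@dataclass(frozen=True)
class CRMConfig:
    """Configuration of a community simulation.

    ``c_s2`` is the by-product carrying capacity in units of ``c_s2_unit``
    CFU/ml (default 70 x 1e8 = 7e9 CFU/ml, comparable to the glucose-derived
    carrying capacities so that growth on by-products can rival growth on
    glucose). Solver tolerances apply to the stacked state [N_1..N_n, S, S2].
    """

    s0: float = 20.0  # initial glucose, mM
    t_end: float = 120.0  # h
    dilution_times: tuple[float, ...] = (24.0, 48.0, 72.0, 96.0)
    dilution_factor: float = 200.0
    flux_coeff: float = 10.0  # glucose consumption = flux_coeff * mu
    secretion_threshold: float = 0.3  # 1/h, gate on mu_max
    secretion_fraction: float = 0.5  # of the glucose consumption flux
    presence_threshold: float = 0.005  # fraction of total abundance
    c_s2: float = 70.0
    c_s2_unit: float = 1e8  # CFU/ml per c_s2 unit
    rtol: float = 1e-8
    atol_n: float = 1e-3  # CFU/ml
    atol_s: float = 1e-12  # mM

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if any(not (0 < t < self.t_end) for t in self.dilution_times):
            raise ValueError("dilution_times must lie strictly within (0, t_end)")
        if self.presence_threshold <= 0 or self.presence_threshold >= 1:
            raise ValueError("presence_threshold must lie in (0, 1)")
        if self.secretion_threshold <= 0:
            raise ValueError("secretion_threshold must be positive")

    @property
    def output_times(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + 0.5, 1.0)

    @property
    def c_s2_abs(self) -> float:
        return self.c_s2 * self.c_s2_unit


@dataclass
class Trajectory:
    """Simulated community state sampled on the hourly output grid.

    The value stored at a dilution time is the pre-dilution state; the exact
    post-dilution state is kept in ``post_dilution`` (time -> state vector of
    [N_1..N_n, S, S2]).
    """

    times: np.ndarray
    abundances: pd.DataFrame  # strains x times, CFU/ml
    glucose: np.ndarray  # mM
    second_carbon: np.ndarray  # mM
    realized_rates: pd.DataFrame  # strains x times, 1/h (on glucose)
    post_dilution: dict[float, np.ndarray] = field(default_factory=dict)
    model: str = "default"


@dataclass
class RichnessSeries:
    times: np.ndarray
    richness: pd.DataFrame  # times x groups, in [0, 1]
    band_min: pd.DataFrame | None = None
    band_max: pd.DataFrame | None = None


def monod_rate(mu_max, s, k):
    """Monod kinetics: mu_max * s / (s + k); zero substrate gives zero."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be non-negative")
    return mu_max * s / (s + k)


def derive_params(raw_table: pd.DataFrame, divisor: float = 4.0) -> pd.DataFrame:
    """Derive simulation parameters from an experimental strain table.

    Adds ``carrying_capacity`` = yield_od x cfu_per_od, ``k_s`` = max yield
    over all strains / own yield (so the best-yielding strain has affinity
    1), ``k_s2`` = k_s, ``n0`` = stationary CFU/ml / ``divisor`` (the net
    effect of 1/20 mixing, 1/200 inoculation and the x1000 volume-unit
    conversion) and a ``scaling_factor`` column (default 1/3) for growth on
    the second carbon source.
    """
    required = {"strain_id", "mu_max", "yield_od", "cfu_per_od", "stationary_cfu_ml"}
    missing = required - set(raw_table.columns)
    if missing:
        raise ValueError(f"strain table missing columns: {sorted(missing)}")
    for col in ("mu_max", "yield_od", "cfu_per_od", "stationary_cfu_ml"):
        if (raw_table[col] <= 0).any():
            raise ValueError(f"column {col!r} must be strictly positive")
    out = raw_table.copy().reset_index(drop=True)
    out["carrying_capacity"] = out["yield_od"] * out["cfu_per_od"]
    out["k_s"] = out["yield_od"].max() / out["yield_od"]
    out["k_s2"] = out["k_s"]
    out["n0"] = out["stationary_cfu_ml"] / divisor
    if "scaling_factor" not in out.columns:
        out["scaling_factor"] = 1.0 / 3.0
    if "is_auxotroph" not in out.columns:
        out["is_auxotroph"] = False
    return out


def _required(params: pd.DataFrame) -> None:
    need = {"strain_id", "mu_max", "carrying_capacity", "k_s", "n0"}
    missing = need - set(params.columns)
    if missing:
        raise ValueError(
            f"params missing derived columns {sorted(missing)}; run derive_params first"
        )
    if len(params) == 0:
        raise ValueError("need at least one strain")


def _integrate(
    params: pd.DataFrame, config: CRMConfig, carbon_xfeed: bool
) -> Trajectory:
    _required(params)
    n = len(params)
    mu_max = params["mu_max"].to_numpy(float)
    C = params["carrying_capacity"].to_numpy(float)
    ks = params["k_s"].to_numpy(float)
    ks2 = params.get("k_s2", pd.Series(ks)).to_numpy(float)
    scaling = params.get("scaling_factor", pd.Series(np.full(n, 1 / 3))).to_numpy(float)
    secretes = mu_max >= config.secretion_threshold
    consumes = ~secretes  # slow growers feed on the by-product; sets disjoint
    cs2 = config.c_s2_abs

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        N = np.maximum(y[:n], 0.0)
        S = max(y[n], 0.0)
        S2 = max(y[n + 1], 0.0)
        mu = mu_max * S / (S + ks)
        dN = mu * N * (1.0 - N / C)
        dS = -config.flux_coeff * float(np.sum(mu * N / C)) * S
        dS2 = 0.0
        if carbon_xfeed:
            dS2 = (
                config.flux_coeff
                * config.secretion_fraction
                * float(np.sum(mu[secretes] * N[secretes] / C[secretes]))
                * S
            )
            mu2 = np.zeros(n)
            mu2[consumes] = mu_max[consumes] * scaling[consumes] * S2 / (S2 + ks2[consumes])
            dN = dN + mu2 * N * (1.0 - N / cs2)
        out = np.empty(n + 2)
        out[:n] = dN
        out[n] = dS
        out[n + 1] = dS2
        return out

    y = np.concatenate([params["n0"].to_numpy(float), [config.s0, 0.0]])
    grid = config.output_times
    boundaries = [0.0, *sorted(config.dilution_times), config.t_end]
    atol = np.concatenate(
        [np.full(n, config.atol_n), [config.atol_s, config.atol_s]]
    )
    stored = {0.0: y.copy()}
    post_dilution: dict[float, np.ndarray] = {}
    for a, b in itertools.pairwise(boundaries):
        t_eval = grid[(grid > a) & (grid <= b)]
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            t_eval=np.unique(np.concatenate([t_eval, [b]])),
            method="RK45",
            rtol=config.rtol,
            atol=atol,
            max_step=1.0,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on [{a}, {b}]: {sol.message}")
        for tk, yk in zip(sol.t, sol.y.T):
            if tk in grid:
                stored[float(tk)] = yk.copy()
        y = sol.y[:, -1].copy()
        if np.any(y[:n] < -config.atol_n):
            warnings.warn("abundance fell below -atol; clipping to zero")
        y[: n + 2] = np.maximum(y, 0.0)
        if b in config.dilution_times:
            y[:n] = y[:n] / config.dilution_factor
            y[n] = config.s0
            y[n + 1] = y[n + 1] / config.dilution_factor
            post_dilution[float(b)] = y.copy()

    times = np.array(sorted(stored))
    states = np.stack([stored[t] for t in times], axis=1)
    N = np.maximum(states[:n], 0.0)
    S = np.maximum(states[n], 0.0)
    S2 = np.maximum(states[n + 1], 0.0)
    rates = mu_max[:, None] * S[None, :] / (S[None, :] + ks[:, None])
    idx = pd.Index(params["strain_id"], name="strain")
    return Trajectory(
        times=times,
        abundances=pd.DataFrame(N, index=idx, columns=times),
        glucose=S,
        second_carbon=S2,
        realized_rates=pd.DataFrame(rates, index=idx, columns=times),
        post_dilution=post_dilution,
        model="carbon_xfeed" if carbon_xfeed else "default",
    )


def simulate_default(params: pd.DataFrame, config: CRMConfig = CRMConfig()) -> Trajectory:
    """Integrate the default single-resource model with serial dilutions."""
    return _integrate(params, config, carbon_xfeed=False)


def simulate_carbon_xfeed(params: pd.DataFrame, config: CRMConfig = CRMConfig()) -> Trajectory:
    """Integrate the carbon cross-feeding extension.

    Strains with mu_max >= ``secretion_threshold`` secrete the second carbon
    source at ``secretion_fraction`` of their glucose consumption flux;
    strains below the threshold additionally grow on it at
    mu_max * scaling_factor * S2/(S2 + K_S2) with carrying capacity
    ``c_s2``. S2 starts at 0 and is diluted with the culture at transfers.
    """
    if config.secretion_threshold > params["mu_max"].max():
        warnings.warn("secretion threshold above every mu_max; no strain secretes")
    return _integrate(params, config, carbon_xfeed=True)


def simulate_vitamin_xfeed(
    params_low: pd.DataFrame,
    params_high: pd.DataFrame,
    config: CRMConfig = CRMConfig(),
) -> Trajectory:
    """Integrate the vitamin cross-feeding extension.

    ``params_high`` maps a subset of strain IDs to their yield at 10 uM
    vitamins (column ``yield_od_10uM``). Covered strains get carrying
    capacity yield_10uM x cfu_per_od; uncovered strains are imputed with the
    mean fold-increase of the covered ones. Affinities are re-derived from
    the effective yields, then the default model is run.
    """
    _required(params_low)
    out = params_low.copy().reset_index(drop=True)
    high = params_high.set_index("strain_id")["yield_od_10uM"]
    covered = out["strain_id"].isin(high.index)
    if not covered.any():
        raise ValueError("params_high covers no strain; cannot impute fold-increase")
    c_low = out["carrying_capacity"].to_numpy(float).copy()
    c_new = c_low.copy()
    cov_idx = np.flatnonzero(covered.to_numpy())
    for i in cov_idx:
        c_new[i] = high.loc[out.loc[i, "strain_id"]] * out.loc[i, "cfu_per_od"]
    fold = float(np.mean(c_new[cov_idx] / c_low[cov_idx]))
    for i in np.flatnonzero(~covered.to_numpy()):
        c_new[i] = c_low[i] * fold
    out["carrying_capacity"] = c_new
    eff_yield = c_new / out["cfu_per_od"].to_numpy(float)
    out["k_s"] = eff_yield.max() / eff_yield
    out["k_s2"] = out["k_s"]
    traj = _integrate(out, config, carbon_xfeed=False)
    traj.model = "vitamin_xfeed"
    return traj


def species_richness(
    trajectory: Trajectory,
    group_labels: Mapping[str, str] | pd.Series,
    presence_threshold: float = 0.005,
) -> RichnessSeries:
    """Detected / introduced fraction per group over the output grid.

    A strain is detected at a time point when its share of total abundance
    is at or above ``presence_threshold``; a zero total abundance raises.
    """
    if not (0 < presence_threshold < 1):
        raise ValueError("presence_threshold must lie in (0, 1)")
    lab = pd.Series(group_labels).reindex(trajectory.abundances.index)
    if lab.isna().any():
        raise ValueError("group_labels must cover every strain")
    N = trajectory.abundances.to_numpy(float)
    total = N.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("total abundance is zero at some time point")
    detected = (N / total[None, :]) >= presence_threshold
    cols = {}
    for g in sorted(lab.unique()):
        members = (lab == g).to_numpy()
        cols[g] = detected[members].sum(axis=0) / members.sum()
    return RichnessSeries(
        times=trajectory.times,
        richness=pd.DataFrame(cols, index=trajectory.times),
    )


_MODELS: dict[str, Callable[[pd.DataFrame, CRMConfig], Trajectory]] = {
    "default": simulate_default,
    "carbon_xfeed": simulate_carbon_xfeed,
}


def sensitivity_bands(
    model_fn: str | Callable[[pd.DataFrame, CRMConfig], Trajectory],
    params: pd.DataFrame,
    config: CRMConfig,
    grids: Mapping[str, Sequence[float]],
    group_labels: Mapping[str, str] | pd.Series | None = None,
) -> RichnessSeries:
    """Pointwise min/max richness envelopes over a parameter grid.

    ``grids`` maps parameter names to value lists; supported names are any
    ``CRMConfig`` field (e.g. ``presence_threshold``, ``secretion_threshold``)
    plus ``aux_scaling_factor`` (the by-product efficiency of auxotrophic
    strains). The returned series is the mid-grid run; band_min/band_max are
    the envelopes. Grid points whose solve fails are skipped with a warning.
    """
    if isinstance(model_fn, str):
        model_fn = _MODELS[model_fn]
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grids must be non-empty")
    if group_labels is None:
        group_labels = pd.Series(
            np.where(params["is_auxotroph"], "auxotrophs", "prototrophs"),
            index=params["strain_id"],
        )
    names = sorted(grids)
    values = [list(grids[k]) for k in names]
    mid_combo = tuple(v[len(v) // 2] for v in values)

    results: dict[tuple, pd.DataFrame] = {}
    for combo in itertools.product(*values):
        cfg = config
        p = params
        for name, val in zip(names, combo):
            if name == "aux_scaling_factor":
                p = p.copy()
                p.loc[p["is_auxotroph"].astype(bool), "scaling_factor"] = val
            elif hasattr(cfg, name):
                cfg = replace(cfg, **{name: val})
            else:
                raise KeyError(f"unknown grid parameter {name!r}")
        try:
            traj = model_fn(p, cfg)
        except RuntimeError as exc:  # solver failure at this grid point
            warnings.warn(f"grid point {dict(zip(names, combo))} skipped: {exc}")
            continue
        results[combo] = species_richness(
            traj, group_labels, presence_threshold=cfg.presence_threshold
        ).richness
    if not results:
        raise RuntimeError("every grid point failed")
    stack = list(results.values())
    band_min = stack[0].copy()
    band_max = stack[0].copy()
    for df in stack[1:]:
        band_min = np.minimum(band_min, df)
        band_max = np.maximum(band_max, df)
    mid = results.get(mid_combo, stack[0])
    return RichnessSeries(
        times=mid.index.to_numpy(float),
        richness=mid,
        band_min=band_min,
        band_max=band_max,
    )
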