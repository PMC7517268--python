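"""Per-state Phi statistics, threshold-grid surfaces and integrity
comparisons.

``<Phi(N)>`` and ``sigma^2(Phi(N))`` are the unweighted mean and
population variance over all 2**N collective states (not weighted by
state occupancy).  Surfaces evaluate encode -> TPM -> Phi per grid cell;
the Phi scope defaults to the main complex, with full-system values
available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._bitops import state_to_bits
from .iit_core.engine import PhiCalculator, main_complex, _relabel_result
from .iit_core.types import PhiResult, StateByNodeTPM
from .state_encoding import (
    GlobalThresholds,
    LocalThresholds,
    Trajectory,
    global_collective_state,
    local_collective_state,
)
from .tpm_estimation import estimate_tpm

__all__ = [
    "PhiSurface",
    "phi_per_state",
    "mean_phi",
    "variance_phi",
    "fano",
    "phi_surface",
    "normalized_surface",
    "weighted_mean_position",
    "top_k_mean",
    "local_global_difference",
    "phi_fano_correlation",
    "random_markov_phi_variances",
    "DEFAULT_LOCAL_GRID",
    "DEFAULT_GLOBAL_GRID",
]

#: default threshold grids (config-driven; the union of values named in the
#: analysis they mirror)
DEFAULT_LOCAL_GRID: Dict[str, tuple] = {
    "xi_D": (50.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1000.0),
    "xi_VF": tuple(
        np.pi * f for f in (0.18, 0.36, 0.56, 0.75, 1.0, 1.2, 1.4, 1.6, 1.8, 1.9, 2.0)
    ),
    "xi_TR": (0.0, 0.001, 0.005, 0.01, 0.05, 0.1),
}
DEFAULT_GLOBAL_GRID: Dict[str, tuple] = {
    "Xi_CM": (100.0, 200.0, 300.0, 400.0, 500.0, 600.0),
    "Xi_AD": tuple(np.pi * f for f in (1 / 16, 1 / 8, 1 / 4, 1 / 2, 3 / 4, 1.0)),
}


# ----------------------------------------------------------------------
# per-state Phi
# ----------------------------------------------------------------------
def phi_per_state(
    tpm,
    scope: str = "main_complex",
    cut_scheme: str = "cut_one",
) -> Dict[int, PhiResult]:
    """One PhiResult per collective state (keyed by the state integer).

    ``scope='full_system'`` evaluates the whole network; ``'main_complex'``
    searches all subsets of size >= 2 per state.
    """
    probs = tpm.probabilities if isinstance(tpm, StateByNodeTPM) else StateByNodeTPM(tpm).probabilities
    n = probs.shape[1]
    out: Dict[int, PhiResult] = {}
    if scope == "full_system":
        calc = PhiCalculator(probs, cut_scheme=cut_scheme)
        for s in range(2**n):
            bits = state_to_bits(s, n)
            out[s] = _relabel_result(calc.big_phi(bits), tuple(range(n)), bits)
    elif scope == "main_complex":
        for s in range(2**n):
            _, res = main_complex(probs, state_to_bits(s, n), cut_scheme=cut_scheme)
            out[s] = res
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return out


def _phi_values(per_state: Mapping[int, object]) -> np.ndarray:
    vals = []
    for key in sorted(per_state):
        v = per_state[key]
        vals.append(v.big_phi if isinstance(v, PhiResult) else float(v))
    return np.asarray(vals, dtype=float)


def mean_phi(per_state) -> float:
    """Unweighted mean of Phi over all collective states."""
    return float(_phi_values(per_state).mean())


def variance_phi(per_state) -> float:
    """Population variance (ddof=0) of Phi over all collective states."""
    return float(_phi_values(per_state).var())


def fano(mean: float, var: float) -> Optional[float]:
    """Normalised variance sigma^2 / <Phi>; None when the mean is zero."""
    if mean == 0:
        return None
    return var / mean


# ----------------------------------------------------------------------
# surfaces
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PhiSurface:
    """Grid of <Phi(N)> / sigma^2(Phi(N)) cells over threshold parameters.

    ``table`` is long-format: one row per cell with the axis coordinates,
    ``mean_phi``, ``var_phi`` and ``fano`` (NaN when undefined).
    ``per_state`` maps the cell row index to its 2**N per-state Phi values.
    """

    table: pd.DataFrame
    axes: Dict[str, tuple]
    dt_frames: int
    n_individuals: int
    scope: str
    setting: str
    per_state: Dict[int, np.ndarray]

    def __post_init__(self) -> None:
        expected = int(np.prod([len(v) for v in self.axes.values()]))
        if len(self.table) != expected:
            raise ValueError("cell count must equal the product of axis lengths")
        if (self.table["mean_phi"] < -1e-12).any() or (self.table["var_phi"] < -1e-12).any():
            raise ValueError("mean_phi and var_phi must be non-negative")

    @property
    def axis_names(self) -> Tuple[str, ...]:
        return tuple(self.axes)

    def to_csv(self, path) -> None:
        df = self.table.copy()
        df["dt_frames"] = self.dt_frames
        df["n"] = self.n_individuals
        df["scope"] = self.scope
        df["setting"] = self.setting
        df.to_csv(path, index=False)


def _thresholds_for(setting: str, coords: Mapping[str, float]):
    if setting == "local":
        return LocalThresholds(coords["xi_D"], coords["xi_VF"], coords["xi_TR"])
    if setting == "global":
        return GlobalThresholds(Xi_AD=coords["Xi_AD"], Xi_CM=coords["Xi_CM"])
    raise ValueError(f"unknown setting {setting!r}")


def phi_surface(
    traj: Trajectory,
    grid: Mapping[str, Sequence[float]],
    dt_frames: int,
    setting: str = "local",
    scope: str = "main_complex",
    cut_scheme: str = "cut_one",
    encode_kwargs: Optional[dict] = None,
) -> PhiSurface:
    """Encode -> estimate TPM -> Phi per state, for every grid cell."""
    encode_kwargs = dict(encode_kwargs or {})
    axes = {k: tuple(v) for k, v in grid.items()}
    n = traj.n_individuals
    rows: List[dict] = []
    per_state: Dict[int, np.ndarray] = {}
    for coords in itertools.product(*axes.values()):
        cell = dict(zip(axes.keys(), coords))
        thr = _thresholds_for(setting, cell)
        if setting == "local":
            seq = local_collective_state(traj, thr, dt_frames, **encode_kwargs)
        else:
            seq = global_collective_state(traj, thr, dt_frames, **encode_kwargs)
        tpm = estimate_tpm(seq)
        results = phi_per_state(tpm, scope=scope, cut_scheme=cut_scheme)
        vals = _phi_values(results)
        m, v = float(vals.mean()), float(vals.var())
        f = fano(m, v)
        idx = len(rows)
        rows.append({**cell, "mean_phi": m, "var_phi": v, "fano": np.nan if f is None else f})
        per_state[idx] = vals
    return PhiSurface(
        table=pd.DataFrame(rows),
        axes=axes,
        dt_frames=dt_frames,
        n_individuals=n,
        scope=scope,
        setting=setting,
        per_state=per_state,
    )


def normalized_surface(surface: PhiSurface, region: Optional[np.ndarray] = None) -> PhiSurface:
    """Scale ``mean_phi`` by the maximum over ``region`` (default: all cells).

    ``region`` is a boolean mask over table rows; the maximum cell of the
    region maps to 1.0.  An all-zero region is an error.
    """
    mask = np.ones(len(surface.table), dtype=bool) if region is None else np.asarray(region, bool)
    if mask.shape != (len(surface.table),):
        raise ValueError("region mask length must match the cell count")
    if not mask.any():
        raise ValueError("region selects no cells")
    peak = surface.table.loc[mask, "mean_phi"].max()
    if peak <= 0:
        raise ValueError("cannot normalize: region maximum <Phi> is zero")
    table = surface.table.copy()
    table["mean_phi"] = table["mean_phi"] / peak
    table["var_phi"] = table["var_phi"] / peak**2
    table["fano"] = table["fano"] / peak
    return replace(surface, table=table, per_state={k: v / peak for k, v in surface.per_state.items()})


def weighted_mean_position(surface: PhiSurface, fraction: float = 0.5) -> Dict[str, float]:
    """Mean cell coordinates weighted by <Phi>, over cells whose <Phi>
    exceeds ``fraction`` of the surface maximum."""
    mp = surface.table["mean_phi"].to_numpy()
    cutoff = fraction * mp.max()
    mask = mp > cutoff
    if not mask.any():
        raise ValueError("no cell exceeds the weighting cutoff")
    w = mp[mask]
    return {
        name: float(np.average(surface.table.loc[mask, name].to_numpy(), weights=w))
        for name in surface.axis_names
    }


def top_k_mean(surface: PhiSurface, k: int = 20) -> float:
    """Mean of the k largest <Phi> cells (the whole surface if k >= #cells)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = np.sort(surface.table["mean_phi"].to_numpy())[::-1]
    return float(vals[: min(k, len(vals))].mean())


def local_global_difference(
    local_surface: PhiSurface, global_surface: PhiSurface, k: int = 20
) -> float:
    """top_k_mean(local) - top_k_mean(global); positive means the global
    (mean-field) setting underestimates the local group integrity."""
    return top_k_mean(local_surface, k) - top_k_mean(global_surface, k)


def phi_fano_correlation(pairs: Iterable[Tuple[float, Optional[float]]]) -> Tuple[float, int]:
    """Pearson correlation between <Phi> and its Fano factor across cells.

    Cells with an undefined Fano factor (None/NaN) are excluded; returns
    (coefficient, number excluded).  The coefficient is NaN when fewer than
    two cells remain or either variable is constant.
    """
    means, fanos = [], []
    n_excluded = 0
    for m, f in pairs:
        if f is None or (isinstance(f, float) and np.isnan(f)):
            n_excluded += 1
            continue
        means.append(float(m))
        fanos.append(float(f))
    if len(means) < 2 or np.std(means) == 0 or np.std(fanos) == 0:
        return float("nan"), n_excluded
    return float(np.corrcoef(means, fanos)[0, 1]), n_excluded


# ----------------------------------------------------------------------
# random homogeneous Markov ensemble (null model for the variance bound)
# ----------------------------------------------------------------------
def random_markov_phi_variances(
    n_nodes: int,
    n_models: int,
    seed: int,
    cut_scheme: str = "cut_one",
) -> np.ndarray:
    """Variance of per-state Phi for an ensemble of random TPMs.

    Each model draws every conditional ON-probability i.i.d. uniform on
    [0, 1]; Phi is computed for all 2**n states over the full system.
    Returns one variance per model.
    """
    from .synthetic_data import random_markov_tpm

    rng = np.random.default_rng(seed)
    out = np.empty(n_models)
    for m in range(n_models):
        tpm = random_markov_tpm(n_nodes, seed=int(rng.integers(2**31 - 1)))
        calc = PhiCalculator(tpm.probabilities, cut_scheme=cut_scheme)
        vals = [calc.big_phi(state_to_bits(s, n_nodes)).big_phi for s in range(2**n_nodes)]
        out[m] = float(np.var(vals))
    return out
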