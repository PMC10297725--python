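"""Parameter-sweep experiment drivers with CSV output.

These functions reproduce the study designs the model is meant for:
MMCA-vs-simulation prevalence curves over the infection probability,
threshold curves over the media broadcast proportion, and the
fragmentation curve of the epidemic layer under targeted edge removal.
Each driver averages over several seeded network realisations and returns
a tidy DataFrame with per-seed rows plus aggregate rows; CSVs carry a
provenance header so re-runs are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import DynamicsParams, MMCAState, iterate_to_stationary
from .network import (
    MultiplexNetwork,
    RsMode,
    couple_layers,
    fragment_after_media_removal,
    generate_layer,
    interlayer_rank_correlation,
    media_mask,
)
from .simulate import run_ensemble
from .threshold import epidemic_threshold, threshold_by_scan, ScanRangeError

log = logging.getLogger("mediaplex")

__all__ = ["NetworkSpec", "SweepSpec", "build_network", "sweep_beta",
           "threshold_curve", "fragment_curve", "write_csv"]


@dataclass(frozen=True)
class NetworkSpec:
    """How to generate one multiplex realisation."""

    n_nodes: int = 1000
    exponent: float = 2.5
    mean_degree_info: float = 10.0
    mean_degree_epi: float = 5.0
    rs_mode: RsMode = "none"


@dataclass(frozen=True)
class SweepSpec:
    """A parameter sweep: grid, fixed dynamics, networks, method."""

    grid_param: str
    grid: tuple[float, ...]
    params: DynamicsParams
    network: NetworkSpec = field(default_factory=NetworkSpec)
    n_network_seeds: int = 10
    method: str = "both"  # mmca | mc | both
    n_runs: int = 1000
    t_max: int = 200
    tail: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid or list(self.grid) != sorted(self.grid):
            raise ValueError("grid must be nonempty and ascending")
        if self.method not in {"mmca", "mc", "both"}:
            raise ValueError(f"unknown method {self.method!r}")


def build_network(spec: NetworkSpec, seed: int) -> MultiplexNetwork:
    """Generate both layers and couple them; seeds derive from ``seed``."""
    info = generate_layer(spec.n_nodes, spec.exponent, spec.mean_degree_info, seed=2 * seed)
    epi = generate_layer(spec.n_nodes, spec.exponent, spec.mean_degree_epi, seed=2 * seed + 1)
    net = couple_layers(info, epi, spec.rs_mode, seed=seed)
    log.info(
        "network seed=%d: info %d edges, epi %d edges, rs=%s (spearman %.3f)",
        seed, info.n_edges, epi.n_edges, spec.rs_mode, interlayer_rank_correlation(net),
    )
    return net


def _mmca_stationary(params: DynamicsParams, net: MultiplexNetwork, mask) -> float:
    res = iterate_to_stationary(
        MMCAState.homogeneous(net.n_nodes, params.rho0), params, net, mask
    )
    if not res.converged:
        log.warning("MMCA not converged (residual %.2e)", res.residual)
    return res.rho_i


def _aggregate(df: pd.DataFrame, by: list[str], values: list[str]) -> pd.DataFrame:
    agg = df.groupby(by, as_index=False)[values].mean()
    agg["network_seed"] = -1
    agg["aggregate"] = True
    df = df.copy()
    df["aggregate"] = False
    return pd.concat([df, agg], ignore_index=True)


def sweep_beta(spec: SweepSpec) -> pd.DataFrame:
    """Stationary prevalence versus infection probability β.

    Returns per-(network seed, β) rows with MMCA and/or ensemble estimates,
    plus aggregate rows (network_seed = -1) averaging over seeds.
    """
    if spec.grid_param != "beta_u":
        raise ValueError("sweep_beta sweeps beta_u")
    rows = []
    for s in range(spec.n_network_seeds):
        net = build_network(spec.network, seed=spec.seed + s)
        mask = media_mask(net, spec.params.eta, spec.params.m)
        for beta in spec.grid:
            p = spec.params.replace(beta_u=float(beta))
            row = {"network_seed": spec.seed + s, "beta_u": float(beta)}
            if spec.method in {"mmca", "both"}:
                row["rho_i_mmca"] = _mmca_stationary(p, net, mask)
            if spec.method in {"mc", "both"}:
                sim = run_ensemble(
                    p, net, mask, n_runs=spec.n_runs, t_max=spec.t_max,
                    tail=spec.tail, seed=spec.seed + s,
                )
                row["rho_i_mc"] = sim.rho_i
                row["rho_i_mc_se"] = sim.rho_i_se
            rows.append(row)
    df = pd.DataFrame(rows)
    values = [c for c in ("rho_i_mmca", "rho_i_mc", "rho_i_mc_se") if c in df]
    return _aggregate(df, ["beta_u"], values)


def threshold_curve(
    spec: SweepSpec,
    rs_modes: Sequence[RsMode] = ("negative", "none", "positive"),
    with_scan: bool = False,
    scan_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Epidemic threshold βc versus media proportion η, per coupling mode."""
    if spec.grid_param != "eta":
        raise ValueError("threshold_curve sweeps eta")
    rows = []
    for rs in rs_modes:
        net_spec = NetworkSpec(**{**spec.network.__dict__, "rs_mode": rs})
        for s in range(spec.n_network_seeds):
            net = build_network(net_spec, seed=spec.seed + s)
            for eta in spec.grid:
                mask = media_mask(net, float(eta), spec.params.m)
                p = spec.params.replace(eta=float(eta))
                th = epidemic_threshold(p, net, mask)
                row = {
                    "eta": float(eta),
                    "rs_mode": rs,
                    "network_seed": spec.seed + s,
                    "beta_c": th.beta_c,
                    "lambda_max": th.lambda_max,
                    "degenerate": th.degenerate,
                }
                if with_scan:
                    grid = scan_grid if scan_grid is not None else np.linspace(0.005, 0.9, 25)
                    try:
                        row["beta_c_scan"] = threshold_by_scan(p, net, mask, grid)
                    except ScanRangeError:
                        row["beta_c_scan"] = float("nan")
                rows.append(row)
    df = pd.DataFrame(rows)
    values = [c for c in ("beta_c", "lambda_max", "beta_c_scan") if c in df]
    return _aggregate(df, ["eta", "rs_mode"], values)


def fragment_curve(
    spec: SweepSpec,
    rs_modes: Sequence[RsMode] = ("negative", "none", "positive"),
) -> pd.DataFrame:
    """Component count of the epidemic layer after targeted edge removal."""
    if spec.grid_param != "eta":
        raise ValueError("fragment_curve sweeps eta")
    rows = []
    for rs in rs_modes:
        net_spec = NetworkSpec(**{**spec.network.__dict__, "rs_mode": rs})
        for s in range(spec.n_network_seeds):
            net = build_network(net_spec, seed=spec.seed + s)
            for eta in spec.grid:
                rows.append({
                    "eta": float(eta),
                    "rs_mode": rs,
                    "network_seed": spec.seed + s,
                    "n_components": fragment_after_media_removal(net, float(eta)),
                })
    df = pd.DataFrame(rows)
    return _aggregate(df, ["eta", "rs_mode"], ["n_components"])


def write_csv(df: pd.DataFrame, path: str | Path, provenance: dict) -> None:
    """Write a CSV with a deterministic provenance header (# key = value)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"# mediaplex {__version__}\n")
        for key in sorted(provenance):
            fh.write(f"# {key} = {provenance[key]}\n")
        df.to_csv(fh, index=False)
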