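"""Planted hierarchical networks and simulated time-series expression.

The generator stands in for an unreleased drought-stress RNA-seq design:
a small directed acyclic regulator hierarchy (default three layers), a
time course of a handful of points with three biological replicates each,
and linear regulation with additive Gaussian noise.

Generative model
----------------
Top-layer regulators receive smooth, mutually orthogonal time profiles
(random low-order polynomial trend + sinusoid, Gram–Schmidt orthonormalized,
standardized to zero mean / unit sd across samples).  Every gene's observed
profile is

    observed(g) = signal(g) + noise(g),
    signal(g)   = sum over parents p of  w_{p→g} · observed(p)

where the noise is replicate-level white noise with sd equal to
``noise_sd`` × sd(signal(g)).  Children are driven by their parents'
*observed* (noisy) profiles: biological replicate variation originates in
the regulator and propagates to its targets.  That choice is what makes
direct regulation identifiable by a first-order partial correlation —
conditioning on the direct parent removes the shared replicate noise,
while conditioning on a more distant ancestor does not.

Linear-additive regulation is used because Pearson/partial-correlation
screening is exactly consistent under linearity, making the planted
networks a fair test bed for the inference method.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    ExpressionMatrix,
    GeneCatalog,
    ROLE_REGULATOR,
    ROLE_STRUCTURAL,
    write_expression_table,
    write_gene_catalog,
)

__all__ = [
    "PlantedEdge",
    "PlantedNetwork",
    "generate_planted_network",
    "simulate_expression",
    "make_gene_catalog",
    "write_truth_edges",
    "read_truth_edges",
    "write_simulation_bundle",
]

# default study-shaped conditions: 8 time points × 3 replicates gives
# n = 24 libraries, enough power for p < .001 at r ≈ .8; relative noise 0.1
DEFAULT_N_TIMEPOINTS = 8
DEFAULT_N_REPLICATES = 3
DEFAULT_NOISE_SD = 0.1
DEFAULT_WEIGHT_RANGE = (0.5, 1.5)
DEFAULT_FAN_OUT = 3
DEFAULT_LAYER_SIZES = (2, 4, 12)

# weights are resampled while |w| falls inside this zero-neighborhood
_MIN_ABS_WEIGHT = 1e-2


@dataclass(frozen=True)
class PlantedEdge:
    regulator: str
    target: str
    weight: float


@dataclass
class PlantedNetwork:
    """Ground-truth hierarchy: disjoint layers (index 0 = top), weighted
    adjacent-layer edges, and the simulation parameters that go with it."""

    layers: List[Set[str]]
    edges: List[PlantedEdge]
    noise_sd: float = DEFAULT_NOISE_SD
    n_timepoints: int = DEFAULT_N_TIMEPOINTS
    n_replicates: int = DEFAULT_N_REPLICATES
    seed: int = 0

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for layer in self.layers:
            if seen & set(layer):
                raise ValueError("layers are not disjoint")
            seen |= set(layer)
        idx: Dict[str, int] = {}
        for i, layer in enumerate(self.layers):
            for g in layer:
                idx[g] = i
        with_parent: Set[str] = set()
        for e in self.edges:
            if idx.get(e.target) != idx.get(e.regulator, -99) + 1:
                raise ValueError(f"edge {e.regulator}->{e.target} not adjacent downward")
            if e.weight == 0:
                raise ValueError("planted weights must be nonzero")
            with_parent.add(e.target)
        for layer in self.layers[1:]:
            orphans = set(layer) - with_parent
            if orphans:
                raise ValueError(f"non-top genes without a parent: {sorted(orphans)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")

    @property
    def layer_sizes(self) -> Tuple[int, ...]:
        return tuple(len(l) for l in self.layers)

    @property
    def gene_ids(self) -> List[str]:
        return [g for layer in self.layers for g in sorted(layer)]

    def edge_keys(self) -> Set[Tuple[str, str]]:
        return {(e.regulator, e.target) for e in self.edges}

    def parents_of(self) -> Dict[str, List[PlantedEdge]]:
        out: Dict[str, List[PlantedEdge]] = {}
        for e in sorted(self.edges, key=lambda e: (e.target, e.regulator)):
            out.setdefault(e.target, []).append(e)
        return out


def _gene_names(layer_sizes: Sequence[int]) -> List[List[str]]:
    width = max(2, len(str(max(layer_sizes))))
    return [
        [f"L{k + 1}G{i + 1:0{width}d}" for i in range(size)]
        for k, size in enumerate(layer_sizes)
    ]


def _draw_weight(rng: np.random.Generator, lo: float, hi: float) -> float:
    for _ in range(1000):
        w = float(rng.uniform(lo, hi))
        if abs(w) >= _MIN_ABS_WEIGHT:
            return w
    raise ValueError(f"weight_range ({lo}, {hi}) lies inside the zero-neighborhood")


def generate_planted_network(
    layer_sizes: Sequence[int] = DEFAULT_LAYER_SIZES,
    fan_out: int = DEFAULT_FAN_OUT,
    weight_range: Tuple[float, float] = DEFAULT_WEIGHT_RANGE,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    n_replicates: int = DEFAULT_N_REPLICATES,
) -> PlantedNetwork:
    """Sample a planted hierarchy: each regulator in layer k picks
    ``fan_out`` distinct targets in layer k+1; a repair pass then gives
    every orphan a random parent (so out-degrees may exceed ``fan_out``).
    Weights are uniform on ``weight_range``, resampled out of a small
    zero-neighborhood.
    """
    if any(s < 1 for s in layer_sizes):
        raise ValueError("layer sizes must all be >= 1")
    if len(layer_sizes) < 1:
        raise ValueError("need at least one layer")
    if fan_out < 1:
        raise ValueError("fan_out must be >= 1")
    lo, hi = weight_range
    if not lo < hi:
        raise ValueError("weight_range must be an interval (lo < hi)")
    for k in range(len(layer_sizes) - 1):
        if fan_out * layer_sizes[k] < layer_sizes[k + 1]:
            raise ValueError(
                f"cannot cover layer {k + 2}: fan_out × {layer_sizes[k]} < "
                f"{layer_sizes[k + 1]}"
            )
    rng = np.random.default_rng(seed)
    names = _gene_names(layer_sizes)
    edges: List[PlantedEdge] = []
    for k in range(len(layer_sizes) - 1):
        regs, targets = names[k], names[k + 1]
        covered: Set[str] = set()
        for r in regs:
            picks = rng.choice(
                len(targets), size=min(fan_out, len(targets)), replace=False
            )
            for t in sorted(targets[i] for i in picks):
                edges.append(PlantedEdge(r, t, _draw_weight(rng, lo, hi)))
                covered.add(t)
        for t in targets:  # repair: guarantee >= 1 parent
            if t not in covered:
                r = regs[int(rng.integers(len(regs)))]
                edges.append(PlantedEdge(r, t, _draw_weight(rng, lo, hi)))
    return PlantedNetwork(
        layers=[set(l) for l in names],
        edges=edges,
        noise_sd=noise_sd,
        n_timepoints=n_timepoints,
        n_replicates=n_replicates,
        seed=int(seed),
    )


def _smooth_basis(
    rng: np.random.Generator, n_top: int, n_timepoints: int
) -> np.ndarray:
    """Random smooth time profiles, orthonormalized across top genes.

    Each raw profile is a low-order polynomial trend plus one sinusoid;
    Gram–Schmidt then enforces linear independence (warning if there are
    more top genes than time points, where exact independence is impossible).
    """
    if n_top > n_timepoints:
        import warnings

        warnings.warn(
            "more top-layer genes than time points: profiles cannot be "
            "linearly independent",
            stacklevel=3,
        )
    tau = np.linspace(0.0, 1.0, n_timepoints)
    raw = np.empty((n_top, n_timepoints))
    for i in range(n_top):
        a = rng.normal(size=3)
        freq = rng.uniform(0.75, 2.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        raw[i] = a[0] * tau + a[1] * tau**2 + a[2] * np.sin(
            2.0 * np.pi * freq * tau + phase
        )
    # Gram-Schmidt against earlier profiles (plus the constant vector, so
    # each profile has nonzero variance after centering)
    basis = np.empty_like(raw)
    ones = np.ones(n_timepoints) / np.sqrt(n_timepoints)
    prev = [ones]
    for i in range(n_top):
        if len(prev) >= n_timepoints:
            # span exhausted (more tops than time points): independence is
            # impossible, fall back to a raw standardized curve
            v = raw[i] - raw[i].mean()
            if np.linalg.norm(v) < 1e-8:
                v = rng.normal(size=n_timepoints)
                v -= v.mean()
            basis[i] = v / np.linalg.norm(v)
            continue
        v = raw[i].copy()
        for u in prev:
            v -= (v @ u) * u
        norm = np.linalg.norm(v)
        while norm < 1e-8:  # degenerate draw: replace with fresh noise curve
            v = rng.normal(size=n_timepoints)
            for u in prev:
                v -= (v @ u) * u
            norm = np.linalg.norm(v)
        v /= norm
        prev.append(v)
        basis[i] = v
    return basis


def simulate_expression(
    net: PlantedNetwork, basis: Optional[np.ndarray] = None
) -> ExpressionMatrix:
    """Simulate the time-series expression matrix for a planted network.

    Samples are ordered time-major: T1R1, T1R2, ..., each with time_point
    and replicate metadata.  ``basis`` optionally fixes the top-layer time
    profiles (shape n_top × n_timepoints); by default they are drawn
    reproducibly from the network's seed.  All profiles are standardized to
    zero mean and unit sd across samples so ``noise_sd`` reads as a
    relative magnitude.
    """
    rng = np.random.default_rng([int(net.seed), 7919])
    T, R = net.n_timepoints, net.n_replicates
    n_samples = T * R
    top = sorted(net.layers[0])
    if basis is None:
        basis = _smooth_basis(rng, len(top), T)
    else:
        basis = np.asarray(basis, dtype=float)
        if basis.shape != (len(top), T):
            raise ValueError(
                f"basis must have shape ({len(top)}, {T}), got {basis.shape}"
            )

    def standardize(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        if sd == 0:
            return v - v.mean()
        return (v - v.mean()) / sd

    observed: Dict[str, np.ndarray] = {}
    parents = net.parents_of()
    for k, layer in enumerate(net.layers):
        for g in sorted(layer):
            if k == 0:
                # time-major layout: each time point's value repeated R times
                signal = standardize(np.repeat(basis[top.index(g)], R))
            else:
                signal = np.zeros(n_samples)
                for e in parents[g]:
                    signal = signal + e.weight * observed[e.regulator]
            sig_sd = signal.std()
            if net.noise_sd > 0 and sig_sd > 0:
                noise = rng.normal(0.0, net.noise_sd * sig_sd, size=n_samples)
            else:
                noise = np.zeros(n_samples)
            observed[g] = signal + noise

    sample_ids = [f"T{t + 1}R{r + 1}" for t in range(T) for r in range(R)]
    genes = net.gene_ids
    values = pd.DataFrame(
        np.vstack([observed[g] for g in genes]), index=genes, columns=sample_ids
    )
    meta = pd.DataFrame(
        {
            "time_point": [str(t + 1) for t in range(T) for _ in range(R)],
            "replicate": [str(r + 1) for _ in range(T) for r in range(R)],
            "condition": ["stress"] * n_samples,
        },
        index=sample_ids,
    )
    return ExpressionMatrix(values=values, sample_meta=meta)


def make_gene_catalog(net: PlantedNetwork) -> GeneCatalog:
    """Bottom layer → structural; every other layer → regulator."""
    roles: Dict[str, str] = {}
    for k, layer in enumerate(net.layers):
        role = ROLE_STRUCTURAL if k == len(net.layers) - 1 else ROLE_REGULATOR
        for g in layer:
            roles[g] = role
    return GeneCatalog(role_by_gene=roles)


def write_truth_edges(net: PlantedNetwork, path, float_fmt: str = "%.6g") -> None:
    idx: Dict[str, int] = {}
    for i, layer in enumerate(net.layers, start=1):
        for g in layer:
            idx[g] = i
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("regulator\ttarget\tweight\tlayer_from\tlayer_to\n")
        for e in sorted(net.edges, key=lambda e: (e.regulator, e.target)):
            fh.write(
                f"{e.regulator}\t{e.target}\t{float_fmt % e.weight}\t"
                f"{idx[e.regulator]}\t{idx[e.target]}\n"
            )


def read_truth_edges(path) -> PlantedNetwork:
    """Rebuild a planted network's structure from its truth-edge TSV.

    Layers are reconstructed from the layer_from/layer_to columns (complete
    because every regulator has a target and every non-top gene a parent).
    Simulation parameters are not stored in the TSV and revert to defaults.
    """
    by_layer: Dict[int, Set[str]] = {}
    edges: List[PlantedEdge] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        need = ("regulator", "target", "weight", "layer_from", "layer_to")
        if not all(c in header for c in need):
            raise ValueError(f"truth edge table must have columns {need}")
        col = {c: header.index(c) for c in need}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            edges.append(
                PlantedEdge(p[col["regulator"]], p[col["target"]], float(p[col["weight"]]))
            )
            by_layer.setdefault(int(p[col["layer_from"]]), set()).add(p[col["regulator"]])
            by_layer.setdefault(int(p[col["layer_to"]]), set()).add(p[col["target"]])
    layers = [by_layer[k] for k in sorted(by_layer)]
    return PlantedNetwork(layers=layers, edges=edges)


def write_simulation_bundle(
    net: PlantedNetwork,
    matrix: ExpressionMatrix,
    outdir,
    extra_params: Optional[dict] = None,
) -> Dict[str, Path]:
    """Write the five-file simulation bundle into ``outdir``.

    expression.tsv, samples.tsv, catalog.tsv, truth_edges.tsv, params.yaml —
    all plain text, byte-stable across runs for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "catalog": outdir / "catalog.tsv",
        "truth_edges": outdir / "truth_edges.tsv",
        "params": outdir / "params.yaml",
    }
    write_expression_table(
        matrix, paths["expression"], meta_path=paths["samples"], float_fmt="%.10g"
    )
    write_gene_catalog(make_gene_catalog(net), paths["catalog"])
    write_truth_edges(net, paths["truth_edges"])
    params = {
        "layer_sizes": list(net.layer_sizes),
        "n_edges": len(net.edges),
        "noise_sd": float(net.noise_sd),
        "n_timepoints": int(net.n_timepoints),
        "n_replicates": int(net.n_replicates),
        "seed": int(net.seed),
    }
    if extra_params:
        params.update(extra_params)
    with paths["params"].open("w", encoding="utf-8") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)
    return paths
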