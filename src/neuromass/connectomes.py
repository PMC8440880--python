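"""Structural connectomes: I/O, normalisation, coupling construction, and
synthetic generation.

A connectome is a square nonnegative matrix of streamline-derived weights
between parcellated brain regions (AAL90 for the healthy presets,
88-region Desikan-Killiany for the patient presets).  Normalisation zeroes
the diagonal and rescales by the maximal remaining entry so weights lie in
[0, 1].  The coupling matrix of the network model is then

    J_kl = sigma * inter_scale * Jtilde_kl   (k != l),
    J_kk = sigma * intra,

with defaults inter_scale = 5 and intra = 20, i.e. strong recurrent
intra-population synapses and inter-population weights in [0, 5*sigma].

The synthetic generator replaces diffusion-MRI data: it emulates the
gross statistics of tractography matrices (approximately log-normal
nonzero weights, sparse, connected, zero diagonal) without claiming
anatomical realism.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ConnectomeMatrix",
    "CouplingMatrix",
    "EZPZSpec",
    "load_connectome",
    "save_connectome",
    "normalize_connectome",
    "build_coupling",
    "generate_synthetic_connectome",
    "generate_ez_pz_fixture",
    "PRESETS",
]

#: cohort presets: healthy AAL90 at sigma=1, patient Desikan-Killiany-88
#: at sigma=1.25 with default excitability eta_bar=-7.5
PRESETS = {
    "healthy": {"n_regions": 90, "sigma": 1.0, "eta_bar": -9.54},
    "patient": {"n_regions": 88, "sigma": 1.25, "eta_bar": -7.5},
}


@dataclass
class ConnectomeMatrix:
    """Square nonnegative structural weight matrix with optional labels."""

    weights: np.ndarray
    labels: list[str] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"connectome must be square, got {W.shape}")
        bad = np.argwhere(~np.isfinite(W) | (W < 0))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"invalid entry at row {i}, col {j}: {W[i, j]}"
            )
        if self.normalized:
            if np.any(np.diag(W) != 0):
                raise ValueError("normalized connectome must have zero diagonal")
            if W.max() > 0 and not np.isclose(W.max(), 1.0):
                raise ValueError("normalized connectome must have max entry 1")
        if self.labels is not None and len(self.labels) != W.shape[0]:
            raise ValueError("label count must match n_regions")
        self.weights = W

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.weights, self.weights.T))


@dataclass
class CouplingMatrix:
    """Synaptic weight matrix of the multipopulation model."""

    J: np.ndarray
    sigma: float = 1.0
    intra: float = 20.0
    inter_scale: float = 5.0

    @property
    def n_pop(self) -> int:
        return self.J.shape[0]


@dataclass
class EZPZSpec:
    """Epileptogenic- and propagation-zone region sets (0-based indices)."""

    ez: frozenset[int]
    pz_clin: frozenset[int] = field(default_factory=frozenset)
    pz_seeg: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.ez = frozenset(int(i) for i in self.ez)
        self.pz_clin = frozenset(int(i) for i in self.pz_clin)
        self.pz_seeg = frozenset(int(i) for i in self.pz_seeg)
        if self.ez & self.pz_seeg:
            raise ValueError("PZ_SEEG must be disjoint from the EZ")

    def validate(self, n_regions: int) -> None:
        for s in (self.ez, self.pz_clin, self.pz_seeg):
            if any(i < 0 or i >= n_regions for i in s):
                raise ValueError("region index out of range")

    def to_json(self, path) -> None:
        """Write as JSON with the conventional 1-based region indices."""
        Path(path).write_text(json.dumps({
            "ez": sorted(i + 1 for i in self.ez),
            "pz_clin": sorted(i + 1 for i in self.pz_clin),
            "pz_seeg": sorted(i + 1 for i in self.pz_seeg),
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "EZPZSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            ez=frozenset(i - 1 for i in d.get("ez", [])),
            pz_clin=frozenset(i - 1 for i in d.get("pz_clin", [])),
            pz_seeg=frozenset(i - 1 for i in d.get("pz_seeg", [])),
        )


def load_connectome(path, fmt: str | None = None) -> ConnectomeMatrix:
    """Read a connectome from a whitespace/CSV matrix file or GraphML.

    The format is inferred from the suffix when ``fmt`` is None.  A label
    sidecar ``<path>.labels`` (one region name per line) is attached when
    present.
    """
    path = Path(path)
    if fmt is None:
        fmt = {
            ".csv": "csv", ".graphml": "graphml",
        }.get(path.suffix.lower(), "whitespace_matrix")
    if fmt == "graphml":
        import networkx as nx

        G = nx.read_graphml(path)
        nodes = list(G.nodes())
        W = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
        labels = [str(n) for n in nodes]
        return ConnectomeMatrix(W, labels=labels, normalized=False)
    delimiter = "," if fmt == "csv" else None
    try:
        W = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as e:
        raise ValueError(f"could not parse {path} as a numeric matrix: {e}")
    if W.shape[0] != W.shape[1]:
        raise ValueError(
            f"{path}: matrix is {W.shape[0]}x{W.shape[1]}, expected square"
        )
    labels = None
    sidecar = path.with_suffix(path.suffix + ".labels")
    if sidecar.exists():
        labels = sidecar.read_text().splitlines()
    return ConnectomeMatrix(W, labels=labels, normalized=False)


def save_connectome(conn: ConnectomeMatrix, path, fmt: str = "csv") -> None:
    path = Path(path)
    delimiter = "," if fmt == "csv" else " "
    np.savetxt(path, conn.weights, delimiter=delimiter, fmt="%.17g")
    if conn.labels is not None:
        path.with_suffix(path.suffix + ".labels").write_text(
            "\n".join(conn.labels)
        )


def normalize_connectome(raw: ConnectomeMatrix) -> ConnectomeMatrix:
    """Zero the diagonal, then rescale by the maximal remaining entry.

    Idempotent and invariant under global rescaling of the raw weights.
    """
    W = raw.weights.copy()
    np.fill_diagonal(W, 0.0)
    m = W.max()
    if m <= 0:
        raise ValueError("cannot normalize an all-zero connectome")
    return ConnectomeMatrix(W / m, labels=raw.labels, normalized=True)


def build_coupling(
    conn: ConnectomeMatrix,
    sigma: float = 1.0,
    intra: float = 20.0,
    inter_scale: float = 5.0,
) -> CouplingMatrix:
    """Coupling matrix J_kl = sigma*inter_scale*Jtilde_kl, J_kk = sigma*intra."""
    if not conn.normalized:
        raise ValueError("build_coupling requires a normalized connectome")
    J = sigma * inter_scale * conn.weights.copy()
    np.fill_diagonal(J, sigma * intra)
    return CouplingMatrix(J=J, sigma=sigma, intra=intra,
                          inter_scale=inter_scale)


def generate_synthetic_connectome(
    n_regions: int = 90,
    density: float = 0.3,
    lognormal_mu: float = -2.0,
    lognormal_sigma: float = 1.0,
    symmetric: bool = True,
    hub_bias: float = 0.0,
    seed: int | None = None,
) -> ConnectomeMatrix:
    """Seeded random connectome with log-normal weights.

    Off-diagonal edges are placed on a random spanning tree first (so the
    graph is always connected) and then at random until the requested
    ``density`` (fraction of off-diagonal pairs) is reached; ``hub_bias``
    in [0, 1] biases extra edges toward a few high-degree regions.
    Nonzero weights are drawn log-normal(mu, sigma) and the matrix is
    normalised to [0, 1] with zero diagonal.
    """
    if n_regions < 2:
        raise ValueError("need at least two regions")
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    n_pairs = n_regions * (n_regions - 1) // 2
    n_edges = int(round(density * n_pairs))
    if n_edges < n_regions - 1:
        raise ValueError(
            f"density {density} too low to connect {n_regions} regions"
        )
    rng = np.random.default_rng(seed)

    # random spanning tree (random node order, attach each to a previous one)
    order = rng.permutation(n_regions)
    edges = set()
    for idx in range(1, n_regions):
        a = order[idx]
        b = order[rng.integers(0, idx)]
        edges.add((min(a, b), max(a, b)))

    # node attractiveness for hub-biased placement
    attract = rng.random(n_regions) ** (1.0 + 9.0 * hub_bias)
    attract /= attract.sum()
    while len(edges) < n_edges:
        need = n_edges - len(edges)
        a = rng.choice(n_regions, size=2 * need + 8, p=attract)
        b = rng.integers(0, n_regions, size=a.size)
        for x, y in zip(a, b):
            if x != y:
                edges.add((min(x, y), max(x, y)))
            if len(edges) >= n_edges:
                break

    W = np.zeros((n_regions, n_regions))
    ii, jj = np.array(sorted(edges)).T
    w = rng.lognormal(lognormal_mu, lognormal_sigma, size=ii.size)
    W[ii, jj] = w
    if symmetric:
        W[jj, ii] = w
    else:
        w2 = rng.lognormal(lognormal_mu, lognormal_sigma, size=ii.size)
        keep = rng.random(ii.size) < 0.9
        W[jj[keep], ii[keep]] = w2[keep]
    return normalize_connectome(ConnectomeMatrix(W))


def generate_ez_pz_fixture(
    conn: ConnectomeMatrix,
    ez_size: int = 1,
    pz_size: int = 3,
    rule: str = "strongest_weight_neighbors",
    seed: int | None = None,
) -> EZPZSpec:
    """Synthetic EZ/PZ specification for testing the evaluation stage.

    The EZ is drawn uniformly (seeded); the PZ collects the top
    ``pz_size`` non-EZ regions either by total weight to the EZ or by
    shortest reciprocal-weight path to the EZ.  Both PZ variants
    (clinician-style and SEEG-style) are set to the same region set.
    """
    n = conn.n_regions
    if ez_size + pz_size >= n:
        raise ValueError("ez_size + pz_size must be < n_regions")
    rng = np.random.default_rng(seed)
    ez = rng.choice(n, size=ez_size, replace=False)
    ez_set = frozenset(int(i) for i in ez)
    others = np.array([i for i in range(n) if i not in ez_set])
    if pz_size == 0:
        return EZPZSpec(ez=ez_set)

    W = conn.weights
    if rule == "strongest_weight_neighbors":
        score = W[np.ix_(others, list(ez_set))].sum(axis=1) \
            + W[np.ix_(list(ez_set), others)].sum(axis=0)
        top = others[np.argsort(-score)][:pz_size]
    elif rule == "shortest_path_neighbors":
        from .netmetrics import weighted_shortest_paths

        D = weighted_shortest_paths(conn).D
        d_to_ez = D[:, list(ez_set)].min(axis=1)[others]
        top = others[np.argsort(d_to_ez)][:pz_size]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    pz = frozenset(int(i) for i in top)
    return EZPZSpec(ez=ez_set, pz_clin=pz, pz_seeg=pz)
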