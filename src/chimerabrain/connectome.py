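"""Structural connectomes and their graph measures.

A structural connectome is a weighted, undirected network of brain
regions.  Edge weights are streamline counts normalized by the summed
volumes of the two endpoint regions, so the adjacency matrix ``A`` is
symmetric, nonnegative and zero on the diagonal.  Each region carries
metadata (hemisphere, cognitive-system label, volume, a 3-D coordinate
in mm) and each connectome belongs to one individual of known age.

The measures implemented here quantify how a region sits inside the
network: the node *strength* :math:`S_k = \\sum_j A_{jk}`, the
*module strength* :math:`S_{k,m} = \\sum_{j \\in m} A_{jk}` with respect
to a partition into modules, the *participation coefficient*
:math:`PC_k = 1 - \\sum_m (S_{k,m}/S_k)^2`, the weighted *rich club*
(a set of high-strength regions more densely interconnected than
expected from their strength alone), and the hop distance from any
region to that rich club.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "RegionInfo",
    "CognitiveParcellation",
    "ModulePartition",
    "Connectome",
    "RichClubConfig",
    "RichClubResult",
    "CANONICAL_SYSTEMS",
    "normalize_by_volume",
    "strength",
    "module_strength",
    "participation_coefficient",
    "rich_club",
    "distance_to_rich_club",
]

#: The nine canonical cognitive systems: attention, auditory,
#: fronto-parietal, cingulo-opercular, motor-sensory, default mode,
#: visual, ventral-temporal and subcortical.
CANONICAL_SYSTEMS = ("Att", "Aud", "FP", "CO", "MS", "DM", "V", "VT", "SC")

SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class RegionInfo:
    """Metadata for one brain region.

    Parameters
    ----------
    name : str
        Region label, unique within a connectome.
    hemisphere : {"left", "right", "none"}
        Hemisphere; subcortical midline structures may use ``"none"``.
    system : str
        Cognitive-system label (one of the parcellation's systems).
    volume : float
        Region volume in arbitrary volume units; must be positive.
    coordinate : tuple of 3 floats
        Centroid coordinate in mm, used only to derive conduction
        delays.
    """

    name: str
    hemisphere: str
    system: str
    volume: float
    coordinate: tuple[float, float, float]

    def __post_init__(self):
        if self.hemisphere not in ("left", "right", "none"):
            raise ValueError(
                f"region {self.name!r}: hemisphere must be left/right/none, "
                f"got {self.hemisphere!r}"
            )
        if not self.volume > 0:
            raise ValueError(f"region {self.name!r}: volume must be > 0")
        object.__setattr__(self, "coordinate", tuple(float(c) for c in self.coordinate))
        if len(self.coordinate) != 3:
            raise ValueError(f"region {self.name!r}: coordinate must be a 3-vector")


@dataclass(frozen=True)
class CognitiveParcellation:
    """Assignment of region indices to cognitive systems.

    ``systems`` is the ordered list of system labels (nine for the
    canonical parcellation) and ``membership`` maps every region index
    to exactly one of them.  ``hemisphere_split`` names systems that
    the *analysis* layer may report per hemisphere (the auditory system
    by default); classification itself always runs on the unsplit
    systems.
    """

    systems: tuple[str, ...]
    membership: dict[int, str]
    hemisphere_split: frozenset[str] = frozenset({"Aud"})

    def __post_init__(self):
        object.__setattr__(self, "systems", tuple(self.systems))
        object.__setattr__(self, "hemisphere_split", frozenset(self.hemisphere_split))
        unknown = set(self.membership.values()) - set(self.systems)
        if unknown:
            raise ValueError(f"membership uses labels not in systems: {sorted(unknown)}")

    @property
    def n_systems(self) -> int:
        return len(self.systems)

    def members(self, system: str) -> np.ndarray:
        """Region indices belonging to ``system`` (sorted)."""
        if system not in self.systems:
            raise KeyError(f"unknown cognitive system {system!r}")
        return np.array(
            sorted(i for i, s in self.membership.items() if s == system), dtype=int
        )

    def labels_array(self, n_regions: int) -> np.ndarray:
        """Per-region integer system ids, ordered like ``systems``."""
        out = np.empty(n_regions, dtype=int)
        index = {s: i for i, s in enumerate(self.systems)}
        for i in range(n_regions):
            try:
                out[i] = index[self.membership[i]]
            except KeyError:
                raise ValueError(f"region {i} is not mapped to any system") from None
        return out

    def as_partition(self, n_regions: int) -> "ModulePartition":
        """View the parcellation as a module partition over ``n_regions``."""
        return ModulePartition(labels=dict(enumerate(self.labels_array(n_regions))))


@dataclass(frozen=True)
class ModulePartition:
    """A partition of region indices into modules.

    Module ids are re-mapped to be contiguous from 0 at construction.
    """

    labels: dict[int, int]

    def __post_init__(self):
        ids = sorted(set(self.labels.values()))
        remap = {m: i for i, m in enumerate(ids)}
        object.__setattr__(
            self, "labels", {k: remap[v] for k, v in self.labels.items()}
        )

    @property
    def module_count(self) -> int:
        return len(set(self.labels.values()))

    def members(self, module: int) -> np.ndarray:
        if module not in set(self.labels.values()):
            raise KeyError(f"unknown module id {module}")
        return np.array(
            sorted(k for k, m in self.labels.items() if m == module), dtype=int
        )

    def labels_array(self, n_regions: int) -> np.ndarray:
        return np.array([self.labels[i] for i in range(n_regions)], dtype=int)


@dataclass(frozen=True)
class Connectome:
    """One individual's structural connectome.

    ``weights`` must be square, nonnegative, zero-diagonal and
    symmetric to within ``1e-12`` (asymmetries inside the tolerance are
    averaged away; larger ones are rejected).
    """

    weights: np.ndarray
    regions: tuple[RegionInfo, ...]
    age: float
    individual_id: str = ""

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weights must be square, got shape {W.shape}")
        if W.shape[0] != len(self.regions):
            raise ValueError(
                f"{W.shape[0]} rows but {len(self.regions)} region records"
            )
        asym = np.abs(W - W.T)
        if asym.size and asym.max() > SYMMETRY_TOL:
            j, k = np.unravel_index(np.argmax(asym), W.shape)
            raise ValueError(
                f"weights not symmetric at ({j}, {k}): "
                f"{W[j, k]!r} vs {W[k, j]!r}"
            )
        W = (W + W.T) / 2.0
        if np.diagonal(W).any():
            k = int(np.flatnonzero(np.diagonal(W))[0])
            raise ValueError(f"nonzero diagonal at region {k}")
        if W.size and W.min() < 0:
            j, k = np.unravel_index(np.argmin(W), W.shape)
            raise ValueError(f"negative weight at ({j}, {k})")
        W.setflags(write=False)
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "regions", tuple(self.regions))

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([r.coordinate for r in self.regions], dtype=float)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([r.volume for r in self.regions], dtype=float)

    def parcellation(
        self, systems: tuple[str, ...] | None = None
    ) -> CognitiveParcellation:
        """Parcellation induced by the regions' system labels.

        ``systems`` fixes the label order; by default the canonical
        nine-system order is used where applicable, with any extra
        labels appended alphabetically.
        """
        present = {r.system for r in self.regions}
        if systems is None:
            systems = tuple(s for s in CANONICAL_SYSTEMS if s in present) + tuple(
                sorted(present - set(CANONICAL_SYSTEMS))
            )
        return CognitiveParcellation(
            systems=systems,
            membership={i: r.system for i, r in enumerate(self.regions)},
        )

    def to_graph(self) -> nx.Graph:
        """Weighted networkx graph (nonzero edges only)."""
        G = nx.Graph()
        for i, r in enumerate(self.regions):
            G.add_node(i, name=r.name, system=r.system, hemisphere=r.hemisphere)
        jj, kk = np.nonzero(np.triu(self.weights, k=1))
        for j, k in zip(jj.tolist(), kk.tolist()):
            G.add_edge(j, k, weight=float(self.weights[j, k]))
        return G


def normalize_by_volume(streamline_counts, volumes) -> np.ndarray:
    """Volume-normalize a streamline-count matrix.

    ``out[j, k] = counts[j, k] / (volumes[j] + volumes[k])`` — each
    edge's streamline count divided by the sum of its two endpoint
    region volumes.

    Raises a ``ValueError`` naming the offending index for asymmetric
    counts, a nonzero diagonal, shape mismatches or non-positive
    volumes.
    """
    C = np.asarray(streamline_counts, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"counts must be square, got shape {C.shape}")
    if v.shape != (C.shape[0],):
        raise ValueError(f"{C.shape[0]} regions but {v.size} volumes")
    if (v <= 0).any():
        k = int(np.flatnonzero(v <= 0)[0])
        raise ValueError(f"non-positive volume at region {k}: {v[k]}")
    asym = C != C.T
    if asym.any():
        j, k = np.unravel_index(np.argmax(asym), C.shape)
        raise ValueError(f"counts not symmetric at ({j}, {k})")
    if np.diagonal(C).any():
        k = int(np.flatnonzero(np.diagonal(C))[0])
        raise ValueError(f"nonzero diagonal count at region {k}")
    return C / (v[:, None] + v[None, :])


def strength(connectome: Connectome) -> np.ndarray:
    """Node strength :math:`S_k = \\sum_j A_{jk}` for every region."""
    return connectome.weights.sum(axis=0)


def module_strength(
    connectome: Connectome, partition: ModulePartition, region: int, module: int
) -> float:
    """Strength of ``region`` restricted to the members of ``module``.

    :math:`S_{k,m} = \\sum_{j \\in m} A_{jk}`.  Summed over all modules
    this recovers the total strength of the region exactly.
    """
    members = partition.members(module)  # raises KeyError for unknown module
    return float(connectome.weights[members, region].sum())


def participation_coefficient(
    connectome: Connectome, partition: ModulePartition | None = None
) -> np.ndarray:
    """Participation coefficient of every region.

    :math:`PC_k = 1 - \\sum_m (S_{k,m}/S_k)^2`.  High values mean the
    region's strength is spread evenly across modules (a connector);
    zero means all its weight stays inside one module.  A region with
    zero strength participates in nothing and gets ``PC = 0``.

    ``partition`` defaults to the cognitive parcellation carried by the
    connectome's region metadata.
    """
    if partition is None:
        partition = connectome.parcellation().as_partition(connectome.n_regions)
    labels = partition.labels_array(connectome.n_regions)
    S = strength(connectome)
    n_m = partition.module_count
    Skm = np.zeros((connectome.n_regions, n_m))
    for m in range(n_m):
        Skm[:, m] = connectome.weights[labels == m, :].sum(axis=0)
    denom = np.where(S > 0, S, 1.0)
    frac = Skm / denom[:, None]
    pc = 1.0 - (frac**2).sum(axis=1)
    pc[S == 0] = 0.0
    return pc


@dataclass(frozen=True)
class RichClubConfig:
    """Knobs for rich-club detection.

    ``n_nulls`` randomized networks are generated by degree-preserving
    edge rewiring followed by rank-based weight placement that
    approximately preserves the strength sequence.  The rich club is
    the top-``r`` strength-ranked set at the largest cutoff, within
    the widest contiguous range where the normalized coefficient
    exceeds 1, that still retains ``membership_fraction`` of the
    range's peak enrichment.
    """

    n_nulls: int = 100
    swaps_per_edge: float = 10.0
    min_nodes: int = 8
    #: smallest cutoff considered a club: a single heavy pair or
    #: triangle is not rich-club structure
    min_club_size: int = 4
    #: membership keeps the largest cutoff in the best contiguous
    #: enriched range whose normalized coefficient retains at least
    #: this fraction of the range's peak enrichment above 1
    membership_fraction: float = 0.5
    seed: int = 0


@dataclass(frozen=True)
class RichClubResult:
    members: frozenset[int]
    #: phi[r] = weighted rich-club coefficient of the top-(r+2) nodes
    cutoffs: np.ndarray
    phi: np.ndarray
    phi_null_mean: np.ndarray
    phi_normalized: np.ndarray


def _weighted_phi(W: np.ndarray, order: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    """Weighted rich-club profile over strength-rank cutoffs.

    phi(r) = total weight among the top-r strength-ranked nodes.  The
    raw profile is meaningless on its own; the rich-club signal is its
    ratio to the same profile on strength-preserving randomized nulls,
    which exposes clubs that are both denser and heavier than their
    members' strengths predict.
    """
    out = np.empty(len(cutoffs))
    for i, r in enumerate(cutoffs):
        club = order[:r]
        out[i] = np.triu(W[np.ix_(club, club)], k=1).sum()
    return out


def _strength_preserving_null(W: np.ndarray, rng: np.random.Generator,
                              swaps_per_edge: float) -> np.ndarray:
    """Randomized network: degree-preserving rewiring, then weights
    re-assigned greedily so node strengths approximate the originals."""
    n = W.shape[0]
    G = nx.from_numpy_array(W)
    n_edges = G.number_of_edges()
    H = G.copy()
    try:
        nx.double_edge_swap(
            H, nswap=int(swaps_per_edge * n_edges),
            max_tries=int(100 * swaps_per_edge * n_edges) + 100,
            seed=int(rng.integers(2**31)),
        )
    except nx.NetworkXException:
        pass  # few or no feasible swaps (e.g. a star); keep what we got
    edges = list(H.edges())
    rng.shuffle(edges)
    weights_sorted = np.sort(W[np.triu_indices_from(W, k=1)])
    weights_sorted = weights_sorted[weights_sorted > 0][::-1]
    target = W.sum(axis=0)
    residual = target.copy()
    B = np.zeros_like(W)
    # place the largest weights on edges whose endpoints still need the
    # most strength (Rubinov-Sporns style rank matching)
    for w in weights_sorted:
        if not edges:
            break
        scores = [residual[a] + residual[b] for a, b in edges]
        i = int(np.argmax(scores))
        a, b = edges.pop(i)
        B[a, b] = B[b, a] = w
        residual[a] -= w
        residual[b] -= w
    return B


def rich_club(connectome: Connectome, config: RichClubConfig | None = None) -> RichClubResult:
    """Detect the weighted rich club of a connectome.

    Computes the weighted rich-club coefficient phi(r) for clubs of the
    top-r strength-ranked regions, normalizes it by the mean of
    ``config.n_nulls`` strength-approximating rewired null networks,
    and returns as members the club at the best-supported cutoff
    inside the widest contiguous run of cutoffs with normalized
    phi > 1: the largest r whose enrichment still reaches
    ``membership_fraction`` of the run's peak (enrichment fades
    gradually as a true club is diluted with non-members, so the knee
    of the profile bounds the club better than its peak).  The member
    set is empty when no cutoff exceeds the null.
    """
    config = config or RichClubConfig()
    n = connectome.n_regions
    if n < config.min_nodes:
        raise ValueError(
            f"graph has {n} nodes; rich-club null generation needs at least "
            f"{config.min_nodes}"
        )
    W = connectome.weights
    S = strength(connectome)
    order = np.argsort(-S, kind="stable")
    cutoffs = np.arange(max(2, config.min_club_size), n)
    phi = _weighted_phi(W, order, cutoffs)

    rng = np.random.default_rng(config.seed)
    null_phis = np.empty((config.n_nulls, len(cutoffs)))
    for i in range(config.n_nulls):
        B = _strength_preserving_null(W, rng, config.swaps_per_edge)
        null_order = np.argsort(-B.sum(axis=0), kind="stable")
        null_phis[i] = _weighted_phi(B, null_order, cutoffs)
    null_mean = null_phis.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_norm = np.where(null_mean > 0, phi / null_mean, 0.0)

    above = phi_norm > 1.0
    members: frozenset[int] = frozenset()
    if above.any():
        # widest contiguous run of cutoffs with normalized phi > 1
        best_run, run_start = None, None
        for i, flag in enumerate(itertools.chain(above, [False])):
            if flag and run_start is None:
                run_start = i
            elif not flag and run_start is not None:
                if best_run is None or (i - run_start) > (best_run[1] - best_run[0]):
                    best_run = (run_start, i)
                run_start = None
        lo, hi = best_run
        peak = phi_norm[lo:hi].max()
        floor = 1.0 + config.membership_fraction * (peak - 1.0)
        eligible = [i for i in range(lo, hi) if phi_norm[i] >= floor]
        i_best = max(eligible)
        members = frozenset(order[: cutoffs[i_best]].tolist())
    return RichClubResult(
        members=members,
        cutoffs=cutoffs,
        phi=phi,
        phi_null_mean=null_mean,
        phi_normalized=phi_norm,
    )


def distance_to_rich_club(
    connectome: Connectome,
    rich_club_members,
    region: int | None = None,
    weighted: bool = False,
):
    """Shortest topological distance from regions to the rich club.

    By default this is the minimum hop count on the binary graph of
    nonzero edges to any rich-club member (0 for members themselves).
    With ``weighted=True`` edge lengths 1/w are used instead.  Regions
    disconnected from every member get ``inf``.

    Returns a float vector over all regions, or a scalar when
    ``region`` is given.
    """
    members = sorted(rich_club_members)
    if not members:
        raise ValueError("rich club is empty")
    G = connectome.to_graph()
    if weighted:
        for _, _, d in G.edges(data=True):
            d["length"] = 1.0 / d["weight"]
        dist = nx.multi_source_dijkstra_path_length(G, set(members), weight="length")
    else:
        dist = nx.multi_source_dijkstra_path_length(G, set(members), weight=None)
    out = np.full(connectome.n_regions, np.inf)
    for k, d in dist.items():
        out[k] = d
    if region is not None:
        return float(out[region])
    return out
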