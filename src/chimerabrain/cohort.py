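"""Seeded generation of synthetic connectome cohorts.

Real multi-site lifespan connectome databases are not redistributable,
so analyses here run on synthetic cohorts that reproduce the
statistical structure the pipeline assumes: 128 regions grouped into
nine cognitive systems (ventral-temporal holding 10 regions and
auditory 3 per hemisphere), symmetric volume-normalized weights with
heavy-tailed strength distributions, a modular block structure with a
densely interlinked rich-club core, and configurable age trajectories
of connectivity.

Age acts on the connectivity *blocks*: each block parameter (density
or weight scale, within- or between-system) follows a trajectory over
the configured age range — constant, linear, monotone decline or an
inverse-U.  The default cohort raises between-system connection
density with age while overall weights decline, so older connectomes
are globally better integrated relative to their modular structure.
Topology-varying age effects are the default mechanism because the
per-connectome critical-coupling calibration of the dynamics module
absorbs any uniform rescaling of the weights; density changes are the
structural feature that survives that calibration.

All randomness flows from a master seed through
``numpy.random.SeedSequence`` spawn keys, so a cohort is exactly
reproducible and any individual can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .connectome import (
    CANONICAL_SYSTEMS,
    CognitiveParcellation,
    Connectome,
    RegionInfo,
)

__all__ = [
    "Trajectory",
    "RegionPlan",
    "CohortConfig",
    "generate_parcellation",
    "generate_connectome",
    "generate_cohort",
    "DEFAULT_REGION_PLAN",
    "DEMO_REGION_PLAN",
]

#: Full-scale region plan: 128 regions over the nine systems.  The
#: ventral-temporal count (10) and per-hemisphere auditory count (3)
#: are anatomical anchors; the subcortical system holds the 14
#: subcortical regions; remaining cortical counts are plausible splits
#: of the 114 cortical parcels.
DEFAULT_REGION_PLAN = {
    "Att": 16,
    "Aud": 6,  # 3 per hemisphere
    "FP": 14,
    "CO": 14,
    "MS": 20,
    "DM": 22,
    "V": 12,
    "VT": 10,
    "SC": 14,
}

#: Desk-scale plan used by the demo pipeline: three regions per system.
DEMO_REGION_PLAN = {s: 3 for s in CANONICAL_SYSTEMS}


@dataclass(frozen=True)
class Trajectory:
    """A scalar parameter's trajectory over age.

    ``kind`` is one of ``constant``, ``linear``, ``power``,
    ``decline`` or ``inverse_u``:

    - ``constant``: always ``lo``.
    - ``linear``: ``lo`` at ``age_min`` rising (or falling) linearly
      to ``hi`` at ``age_max``.
    - ``power``: ``lo + (hi - lo) x^gamma`` with x the age fraction;
      ``gamma > 1`` concentrates the change late in life, ``< 1``
      early.
    - ``decline``: ``hi`` at ``age_min`` falling linearly to ``lo``.
    - ``inverse_u``: quadratic through ``lo`` at both ends peaking at
      ``hi`` at ``peak_age``.
    """

    kind: str = "constant"
    lo: float = 1.0
    hi: float = 1.0
    peak_age: float = 45.0
    gamma: float = 1.0

    def __call__(self, age: float, age_min: float, age_max: float) -> float:
        span = max(age_max - age_min, 1e-9)
        x = np.clip((age - age_min) / span, 0.0, 1.0)
        if self.kind == "constant":
            return self.lo
        if self.kind == "linear":
            return self.lo + (self.hi - self.lo) * x
        if self.kind == "power":
            return self.lo + (self.hi - self.lo) * x**self.gamma
        if self.kind == "decline":
            return self.hi + (self.lo - self.hi) * x
        if self.kind == "inverse_u":
            p = np.clip((self.peak_age - age_min) / span, 1e-6, 1 - 1e-6)
            # quadratic in x with value lo at x=0,1 and hi at x=p
            q = (x - p) ** 2 / max(p, 1 - p) ** 2
            return self.hi + (self.lo - self.hi) * q
        raise ValueError(f"unknown trajectory kind {self.kind!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a cohort.

    ``ages_per_bin`` maps an age-bin label to the list of individual
    ages to draw in that bin; one connectome is generated per listed
    age.  Densities are edge probabilities in [0, 1]; weight scales
    multiply log-normal draws (``sigma_log`` sets the heavy tail).
    The rich-club core is a set of ``core_size`` hub regions (spread
    over the systems) whose mutual connections are complete and
    ``core_weight_mult`` times stronger.
    """

    region_plan: dict[str, int] = field(
        default_factory=lambda: dict(DEMO_REGION_PLAN)
    )
    ages_per_bin: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "young": (8.0, 14.0, 21.0, 27.0),
            "middle": (34.0, 42.0, 50.0, 57.0),
            "old": (63.0, 70.0, 79.0, 87.0),
        }
    )
    age_min: float = 5.0
    age_max: float = 90.0
    density_within: Trajectory = Trajectory("constant", lo=0.8)
    density_between: Trajectory = Trajectory("power", lo=0.08, hi=0.20, gamma=1.7)
    scale_within: Trajectory = Trajectory("constant", lo=1.0)
    scale_between: Trajectory = Trajectory("power", lo=0.10, hi=0.30, gamma=1.7)
    sigma_log: float = 0.45
    core_size: int = 9
    core_weight_mult: float = 2.5
    volume_log_mean: float = 8.0  # exp(8) ~ 3 cm^3 in mm^3
    volume_log_sigma: float = 0.4
    coordinate_extent: tuple[float, float, float] = (70.0, 85.0, 60.0)
    hemisphere_gap: float = 5.0
    #: With pairing, individual i of every age bin shares one random
    #: stream (common random numbers): the bins hold matched network
    #: skeletons that differ only through the age trajectories, the
    #: paired design a small demo cohort needs for age contrasts to
    #: rise above sampling noise.  Without it individuals are fully
    #: independent, as in a real cross-sectional cohort.
    paired_across_bins: bool = True
    master_seed: int = 0

    def __post_init__(self):
        for name in ("density_within", "density_between"):
            t: Trajectory = getattr(self, name)
            if not (0.0 <= t.lo <= 1.0 and 0.0 <= t.hi <= 1.0):
                raise ValueError(f"{name}: densities must lie in [0, 1]")
        if any(c < 1 for c in self.region_plan.values()):
            raise ValueError("region plan counts must be >= 1")
        for ages in self.ages_per_bin.values():
            for a in ages:
                if not (self.age_min <= a <= self.age_max):
                    raise ValueError(
                        f"age {a} outside configured range "
                        f"[{self.age_min}, {self.age_max}]"
                    )

    def to_yaml(self) -> str:
        d = asdict(self)
        for key in ("density_within", "density_between", "scale_within",
                    "scale_between"):
            d[key] = asdict(getattr(self, key))
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortConfig":
        d = yaml.safe_load(text)
        for key in ("density_within", "density_between", "scale_within",
                    "scale_between"):
            if key in d and isinstance(d[key], dict):
                d[key] = Trajectory(**d[key])
        if "ages_per_bin" in d:
            d["ages_per_bin"] = {
                k: tuple(v) for k, v in d["ages_per_bin"].items()
            }
        if "coordinate_extent" in d:
            d["coordinate_extent"] = tuple(d["coordinate_extent"])
        return cls(**d)


def generate_parcellation(
    region_plan: dict[str, int] | None = None,
    config: CohortConfig | None = None,
) -> tuple[CognitiveParcellation, tuple[RegionInfo, ...]]:
    """Build the region list and parcellation for a region plan.

    Deterministic given the plan: region volumes and coordinates are
    drawn from a generator seeded by a fixed key so that repeated calls
    agree bit for bit.  Hemispheres are assigned symmetrically within
    each system (the odd region of an odd count gets ``"none"``), and
    coordinates are placed in two mirrored hemispheric slabs whose
    extent makes inter-region Euclidean distances span roughly
    10-170 mm, the range that yields conduction delays of ~1-17 ms at
    10 m/s.
    """
    config = config or CohortConfig(region_plan=dict(region_plan or DEMO_REGION_PLAN))
    plan = dict(region_plan) if region_plan is not None else config.region_plan
    if not plan:
        raise ValueError("region plan must contain at least one system")
    systems = tuple(s for s in CANONICAL_SYSTEMS if s in plan) + tuple(
        s for s in plan if s not in CANONICAL_SYSTEMS
    )
    # fixed key: parcellation is shared by every individual in a cohort
    rng = np.random.default_rng(np.random.SeedSequence([0xC0C5, len(plan)]))
    ex, ey, ez = config.coordinate_extent
    regions: list[RegionInfo] = []
    membership: dict[int, str] = {}
    for system in systems:
        count = plan[system]
        for i in range(count):
            if count % 2 == 1 and i == count - 1:
                hemi = "none"
            else:
                hemi = "left" if i % 2 == 0 else "right"
            vol = float(np.exp(rng.normal(config.volume_log_mean,
                                          config.volume_log_sigma)))
            u = rng.uniform(-1, 1, size=3)
            x = config.hemisphere_gap + abs(u[0]) * (ex - config.hemisphere_gap)
            if hemi == "left":
                x = -x
            elif hemi == "none":
                x = u[0] * config.hemisphere_gap
            coord = (x, u[1] * ey, u[2] * ez)
            membership[len(regions)] = system
            regions.append(
                RegionInfo(
                    name=f"{system}_{hemi[0].upper()}{i // 2 + 1}"
                    if hemi != "none"
                    else f"{system}_M{i + 1}",
                    hemisphere=hemi,
                    system=system,
                    volume=vol,
                    coordinate=coord,
                )
            )
    parc = CognitiveParcellation(systems=systems, membership=membership)
    return parc, tuple(regions)


def _core_regions(parc: CognitiveParcellation, n_regions: int, core_size: int) -> list[int]:
    """Hub regions forming the rich-club core: the first region of each
    system in order, cycling until ``core_size`` are chosen."""
    per_system = [parc.members(s).tolist() for s in parc.systems]
    core: list[int] = []
    depth = 0
    while len(core) < min(core_size, n_regions):
        for members in per_system:
            if depth < len(members) and len(core) < core_size:
                core.append(members[depth])
        depth += 1
    return core


def generate_connectome(
    age: float,
    config: CohortConfig,
    seed: int | np.random.SeedSequence,
    individual_id: str = "",
) -> Connectome:
    """Draw one synthetic connectome at the given age.

    Weights follow a stochastic block model over cognitive systems:
    within-system blocks are denser and heavier than between-system
    blocks, individual edge weights are log-normal, and the rich-club
    core's mutual edges are complete and up-weighted.  The block
    densities and scales are the configured trajectories evaluated at
    ``age``.
    """
    if not (config.age_min <= age <= config.age_max):
        raise ValueError(f"age {age} outside [{config.age_min}, {config.age_max}]")
    parc, regions = generate_parcellation(config.region_plan, config)
    n = len(regions)
    labels = parc.labels_array(n)
    rng = np.random.default_rng(seed)

    a0, a1 = config.age_min, config.age_max
    d_in = config.density_within(age, a0, a1)
    d_out = config.density_between(age, a0, a1)
    w_in = config.scale_within(age, a0, a1)
    w_out = config.scale_between(age, a0, a1)

    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    p = np.where(same[iu], d_in, d_out)
    scale = np.where(same[iu], w_in, w_out)
    present = rng.random(len(p)) < p
    draws = np.exp(rng.normal(0.0, config.sigma_log, size=len(p)))
    vals = np.where(present, scale * draws, 0.0)

    W = np.zeros((n, n))
    W[iu] = vals
    W = W + W.T

    # hub backbone: complete among the core, with weights on the
    # within-system scale so the club's edges are among the heaviest
    # in the network (a rich club in the weighted sense, not only a
    # dense one)
    core = _core_regions(parc, n, config.core_size)
    mult = config.core_weight_mult
    for a in range(len(core)):
        for b in range(a + 1, len(core)):
            j, k = core[a], core[b]
            base = max(W[j, k], w_in * np.exp(rng.normal(0.0, config.sigma_log)))
            W[j, k] = W[k, j] = base * mult
    return Connectome(
        weights=W, regions=regions, age=float(age), individual_id=individual_id
    )


def generate_cohort(config: CohortConfig) -> list[Connectome]:
    """Generate the whole cohort configured in ``config``.

    Per-individual seeds are spawned from the master seed with the key
    ``[master_seed, bin_index, index_within_bin]`` — or
    ``[master_seed, index_within_bin]`` for a paired cohort, where
    individual ``i`` of every bin shares the stream — so any
    individual is reproducible without generating the others.
    """
    cohort: list[Connectome] = []
    for b, (bin_label, ages) in enumerate(config.ages_per_bin.items()):
        for i, age in enumerate(ages):
            key = (
                [config.master_seed, i]
                if config.paired_across_bins
                else [config.master_seed, b, i]
            )
            seed = np.random.SeedSequence(key)
            cohort.append(
                generate_connectome(
                    age, config, seed,
                    individual_id=f"{bin_label}-{i:02d}",
                )
            )
    return cohort
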