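"""Synthetic resting-state fMRI cohorts with planted network structure.

The generator emulates the statistical structure the stepwise-connectivity
pipeline assumes: each subject is a voxel-by-time matrix whose correlation
structure is driven by a small set of community latent signals wired together
by a weighted community graph.  A seed community sits at graph distance 0 and,
with the default chain topology, community ``c_k`` sits exactly ``k`` link
steps away, so the expected seed-based stepwise maps are known by
construction.  Cohorts carry group labels, age/sex covariates, clinical scores
and an optional planted group effect (a multiplicative modulation of one
community's edges), which downstream recovery tests compare against the
stored ground truth.

Defaults are chosen to mirror a typical 1.5 T resting-state acquisition
analysed on a coarse 5 mm grid: TR = 3 s, 200 volumes, a ~500-voxel
ellipsoidal analysis mask, and cohort sizes of 60 controls, 32 tremor-dominant
and 26 postural-instability subjects (converter subanalysis: 10 vs 18).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NetworkBlueprint",
    "SubjectSpec",
    "GroundTruth",
    "VoxelTimeSeries",
    "make_blueprint",
    "simulate_subject",
    "simulate_cohort",
    "simulate_task_subject",
    "write_cohort",
    "DEFAULT_GROUP_SIZES",
    "CONVERTER_GROUP_SIZES",
]

#: Cohort sizes used throughout: healthy controls, tremor-dominant and
#: postural-instability-gait-disorder Parkinson subtypes.
DEFAULT_GROUP_SIZES = {"HC": 60, "PD_TD": 32, "PD_PIGD": 26}

#: Four-year follow-up subanalysis: tremor-dominant converters vs
#: non-converters to the PIGD subtype.
CONVERTER_GROUP_SIZES = {"cPD_TD": 10, "ncPD_TD": 18}

#: Baseline clinical score distributions (mean, sd) for a mildly affected
#: Parkinson cohort; Hoehn & Yahr stage, UPDRS total and the freezing-of-gait
#: questionnaire.  Healthy controls score ~0 on all three.
CLINICAL_BASELINE = {
    "HY": (1.45, 0.76),
    "UPDRS_total": (30.0, 12.0),
    "FOGQ": (1.50, 1.43),
}

_GROUPS = ("HC", "PD_TD", "PD_PIGD", "cPD_TD", "ncPD_TD")


@dataclass
class NetworkBlueprint:
    """Ground-truth network layout generating one cohort's data.

    ``communities`` maps community label -> flat voxel indices into the
    in-mask voxel list (row order of :func:`numpy.argwhere` on ``mask``).
    ``community_graph`` maps unordered label pairs ``(a, b)`` (a != b) to the
    between-community mixing weight; ``w_in`` is the within-community weight.
    """

    grid_shape: tuple[int, int, int]
    mask: np.ndarray
    communities: dict[str, np.ndarray]
    seed_community: str
    community_graph: dict[tuple[str, str], float]
    w_in: float
    noise_sd: float = 0.6
    tr_seconds: float = 3.0
    n_volumes: int = 200
    band_limit: bool = True
    band_hz: tuple[float, float] = (0.01, 0.08)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def labels(self) -> list[str]:
        return list(self.communities)

    def voxel_coords(self) -> np.ndarray:
        """(m, 3) integer grid coordinates of in-mask voxels, row order fixed."""
        return np.argwhere(self.mask)

    def community_of_voxel(self) -> np.ndarray:
        """Integer community index per in-mask voxel (-1 if unassigned)."""
        out = np.full(self.n_voxels, -1, dtype=int)
        for ci, (_, idx) in enumerate(self.communities.items()):
            out[idx] = ci
        return out

    def expected_r(self, a: str, b: str,
                   effect_map: Mapping[str, float] | None = None) -> float:
        """Expected voxel-voxel Pearson correlation between communities.

        Within a community (``a == b``) this is ``w_in^2 / (w_in^2 + s^2)``;
        between communities it is scaled by the latent correlation implied by
        the community graph (path product of edge weights).
        """
        labels = self.labels
        C = self.latent_covariance(effect_map)
        i, j = labels.index(a), labels.index(b)
        base = self.w_in ** 2 / (self.w_in ** 2 + self.noise_sd ** 2)
        return base if i == j else float(base * C[i, j])

    def latent_covariance(self, effect_map: Mapping[str, float] | None = None) -> np.ndarray:
        """Correlation matrix of the community latent signals.

        Edge weights are the latent correlations of adjacent communities;
        non-adjacent pairs get the product of edge weights along a shortest
        path (exact and positive definite on trees, the default chain).  The
        matrix is eigenvalue-clipped back to positive semidefinite for graph
        topologies where the path-product fill is indefinite.

        A planted effect with multiplier ``m`` on community ``P`` rescales the
        *expected Fisher-z strength* of every community-graph edge touching
        ``P`` by ``m`` — Fisher z being the unit in which the pipeline
        measures connectivity — by solving for the latent edge correlation
        that achieves the target.  Voxel amplitude and within-community
        coherence are untouched, so the modulation is purely a coupling
        change: an amplitude change would move the min-max normalizer of the
        whole association matrix and contaminate every other edge.
        """
        labels = self.labels
        nc = len(labels)
        mult = {lab: 1.0 for lab in labels}
        if effect_map:
            mult.update({k: float(v) for k, v in effect_map.items()})
        base = self.w_in ** 2 / (self.w_in ** 2 + self.noise_sd ** 2)
        edges: dict[tuple[int, int], float] = {}
        for (a, b), rho in self.community_graph.items():
            i, j = labels.index(a), labels.index(b)
            m = max(mult[a], mult[b])
            if m != 1.0:
                # solve for the latent correlation hitting z_target = m * z_base
                z_base = np.arctanh(np.clip(base * rho, -0.999999, 0.999999))
                r_target = np.tanh(m * z_base)
                rho = float(np.clip(r_target / base, 0.0, 0.999))
            edges[(i, j)] = edges[(j, i)] = rho
        # shortest-path product fill via BFS from every node
        C = np.eye(nc)
        for s in range(nc):
            dist = np.full(nc, -1)
            val = np.zeros(nc)
            dist[s], val[s] = 0, 1.0
            frontier = [s]
            while frontier:
                nxt = []
                for u in frontier:
                    for (i, j), rho in edges.items():
                        if i == u and dist[j] < 0:
                            dist[j] = dist[u] + 1
                            val[j] = val[u] * rho
                            nxt.append(j)
                frontier = nxt
            C[s, dist >= 0] = np.where(np.arange(nc)[dist >= 0] == s, 1.0,
                                       val[dist >= 0])
        C = (C + C.T) / 2.0
        evals = np.linalg.eigvalsh(C)
        if evals.min() < 1e-10:
            w, V = np.linalg.eigh(C)
            C = V @ np.diag(np.clip(w, 1e-8, None)) @ V.T
            d = np.sqrt(np.diag(C))
            C = C / np.outer(d, d)
        return C

    def validate(self) -> None:
        seen: set[int] = set()
        for lab, idx in self.communities.items():
            s = set(int(i) for i in idx)
            if seen & s:
                raise ValueError(f"community {lab!r} overlaps another community")
            seen |= s
        if self.seed_community not in self.communities:
            raise ValueError(f"seed community {self.seed_community!r} undefined")
        for (a, b), w in self.community_graph.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"edge weight {w} for ({a},{b}) outside [0, 1]")
            if w >= self.w_in:
                raise ValueError("within-community weight must exceed between weights")
        # fully-null blueprints (all between weights 0) are allowed: they are
        # the independence construction used by calibration tests
        if any(w > 0 for w in self.community_graph.values()):
            if not np.isfinite(list(self.graph_distances().values())).all():
                raise ValueError("community graph is not connected from the seed")

    def graph_distances(self) -> dict[str, float]:
        """Unweighted graph distance (link steps) from the seed community."""
        adj: dict[str, set[str]] = {lab: set() for lab in self.labels}
        for (a, b), w in self.community_graph.items():
            if w > 0:
                adj[a].add(b)
                adj[b].add(a)
        dist = {lab: np.inf for lab in self.labels}
        dist[self.seed_community] = 0
        frontier = [self.seed_community]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[v] == np.inf:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        return dist


@dataclass
class SubjectSpec:
    """One subject's identity, covariates and planted modulation."""

    subject_id: str
    group: str
    age: float
    sex: str  # "F" / "M"
    clinical: dict[str, float] = field(default_factory=dict)
    effect_map: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        hy = self.clinical.get("HY")
        if hy is not None and not (0.0 <= hy <= 5.0):
            raise ValueError("Hoehn & Yahr stage must lie in [0, 5]")
        for k, v in self.clinical.items():
            if v < 0:
                raise ValueError(f"clinical score {k} must be nonnegative")


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    distances: dict[str, int]
    planted_mask: np.ndarray  # 3D boolean, True on the modulated community
    planted_community: str | None
    planted_multiplier: float
    clinical_separation_d: float

    @property
    def effect_size(self) -> float:
        """0 for a global-null cohort, else the fractional edge modulation."""
        if self.planted_multiplier == 1.0 and self.clinical_separation_d == 0.0:
            return 0.0
        return self.planted_multiplier - 1.0


@dataclass
class VoxelTimeSeries:
    """One subject's in-mask voxel x time matrix with grid geometry."""

    data: np.ndarray  # (m voxels, t volumes)
    mask: np.ndarray  # 3D boolean
    tr_seconds: float
    subject_id: str = ""
    affine: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def to_4d(self) -> np.ndarray:
        vol = np.zeros(self.mask.shape + (self.n_volumes,), dtype=np.float32)
        vol[self.mask] = self.data
        return vol

    @classmethod
    def from_4d(cls, img: np.ndarray, mask: np.ndarray, tr_seconds: float,
                subject_id: str = "", affine: np.ndarray | None = None) -> "VoxelTimeSeries":
        return cls(np.asarray(img)[np.asarray(mask, bool)], np.asarray(mask, bool),
                   tr_seconds, subject_id, affine)


def _ellipsoid_mask(grid_shape: Sequence[int]) -> np.ndarray:
    """Centered ellipsoid filling the grid, a stand-in for a brain mask."""
    axes = [np.arange(n) - (n - 1) / 2.0 for n in grid_shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    semi = [max(n / 2.0, 0.5) for n in grid_shape]
    return (zz / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (xx / semi[2]) ** 2 <= 1.0


def make_blueprint(
    grid_shape: Sequence[int] = (10, 10, 10),
    n_communities: int = 4,
    chain_topology: bool = True,
    w_in: float = 0.9,
    w_between: float = 0.75,
    seed: int | None = 0,
    *,
    noise_sd: float = 0.5,
    background_fraction: float = 0.3,
    tr_seconds: float = 3.0,
    n_volumes: int = 200,
    band_limit: bool = True,
    mask: np.ndarray | None = None,
    min_community_size: int = 4,
) -> NetworkBlueprint:
    """Lay out ``n_communities`` spatially compact communities in a mask.

    Communities are contiguous slabs of the in-mask voxels ordered along the
    first grid axis; with ``chain_topology`` the community graph is the chain
    seed - c1 - c2 - ..., so community ``c_k`` sits at graph distance ``k``
    from the seed.  ``chain_topology=False`` wires every pair at ``w_between``
    (complete graph, all non-seed communities at distance 1).  Within each
    slab, ``background_fraction`` of the voxels are left unassigned — pure
    noise voxels emulating tissue uncorrelated with the seeded system.  They
    guarantee genuinely null edges in every association matrix (so its
    off-diagonal minimum is zero and the min-max normalizer is anchored),
    exactly as sub-threshold edges do on real data.  Deterministic given
    ``seed``.
    """
    if n_communities < 2:
        raise ValueError("need at least 2 communities (a seed and one target)")
    if not (0.0 < w_in <= 1.0) or not (0.0 <= w_between <= 1.0):
        raise ValueError("weights must lie in (0, 1]")
    if w_between >= w_in:
        raise ValueError("w_between must be smaller than w_in")
    grid_shape = tuple(int(g) for g in grid_shape)
    if mask is None:
        mask = _ellipsoid_mask(grid_shape)
    mask = np.asarray(mask, bool)
    m = int(mask.sum())
    if m < n_communities * min_community_size:
        raise ValueError(
            f"grid too small: {m} in-mask voxels cannot host "
            f"{n_communities} communities of >= {min_community_size} voxels"
        )
    if not (0.0 <= background_fraction < 1.0):
        raise ValueError("background_fraction must lie in [0, 1)")
    coords = np.argwhere(mask)
    # slab partition along the first axis keeps communities spatially compact
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    chunks = np.array_split(order, n_communities)
    labels = ["seed"] + [f"c{k}" for k in range(1, n_communities)]
    rng = np.random.default_rng(seed)
    communities = {}
    for lab, chunk in zip(labels, chunks):
        keep = max(min_community_size,
                   int(round(len(chunk) * (1.0 - background_fraction))))
        sel = rng.choice(len(chunk), size=min(keep, len(chunk)), replace=False)
        communities[lab] = np.sort(chunk[np.sort(sel)])
    graph: dict[tuple[str, str], float] = {}
    if chain_topology:
        for a, b in zip(labels[:-1], labels[1:]):
            graph[(a, b)] = w_between
    else:
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                graph[(a, b)] = w_between
    bp = NetworkBlueprint(
        grid_shape=grid_shape, mask=mask, communities=communities,
        seed_community="seed", community_graph=graph, w_in=w_in,
        noise_sd=noise_sd, tr_seconds=tr_seconds, n_volumes=n_volumes,
        band_limit=band_limit,
    )
    bp.validate()
    return bp


def _band_limited_noise(rng: np.random.Generator, n_series: int, n_t: int,
                        tr: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian series confined to [low, high] Hz.

    Band-limiting keeps planted correlations intact under the pipeline's own
    band-pass filter; series are standardised empirically so the community
    mixing algebra holds for sample second moments.
    """
    x = rng.standard_normal((n_series, n_t))
    freqs = np.fft.rfftfreq(n_t, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(x, axis=1)
    spec[:, ~keep] = 0.0
    x = np.fft.irfft(spec, n=n_t, axis=1)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _subject_rng(cohort_seed: int | None, subject_index: int) -> np.random.Generator:
    # one stream per subject so a single subject can be regenerated stably
    return np.random.default_rng(np.random.SeedSequence([int(cohort_seed or 0), subject_index]))


def simulate_subject(
    blueprint: NetworkBlueprint,
    spec: SubjectSpec | None = None,
    seed: int | np.random.Generator | None = 0,
    *,
    motion_scale_mm: float = 0.02,
    motion_spikes: Sequence[tuple[int, float]] = (),
) -> tuple[VoxelTimeSeries, np.ndarray]:
    """Simulate one subject's voxel time series and 6-column motion trace.

    Voxel ``v`` in community ``k`` follows
    ``x_v(t) = w_in * u_k(t) + noise_sd * e_v(t)`` with unit-variance
    community latents ``u`` whose correlation matrix is set by the community
    graph (:meth:`NetworkBlueprint.latent_covariance`), so the expected
    voxel-voxel correlation is monotone in the blueprint weights.  The motion
    trace is a smooth low-amplitude random walk (translations mm, rotations
    rad); ``motion_spikes`` injects persistent x-translation jumps of the
    given amplitude at the given frames, producing a framewise displacement
    exactly equal to the amplitude at that frame.
    """
    if blueprint.n_volumes < 50:
        raise ValueError("need at least 50 volumes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    effect = spec.effect_map if spec is not None else None
    C = blueprint.latent_covariance(effect)
    nc, n_t = C.shape[0], blueprint.n_volumes
    m = blueprint.n_voxels

    if blueprint.band_limit:
        sources = _band_limited_noise(rng, nc, n_t, blueprint.tr_seconds, blueprint.band_hz)
        noise = _band_limited_noise(rng, m, n_t, blueprint.tr_seconds, blueprint.band_hz)
    else:
        sources = rng.standard_normal((nc, n_t))
        noise = rng.standard_normal((m, n_t))
    latents = np.linalg.cholesky(C + 1e-12 * np.eye(nc)) @ sources

    comm = blueprint.community_of_voxel()
    data = blueprint.noise_sd * noise
    assigned = comm >= 0
    data[assigned] += blueprint.w_in * latents[comm[assigned]]

    ts = VoxelTimeSeries(
        data=data, mask=blueprint.mask, tr_seconds=blueprint.tr_seconds,
        subject_id=spec.subject_id if spec is not None else "",
    )

    steps = rng.standard_normal((n_t, 6)) * np.array([motion_scale_mm] * 3 + [motion_scale_mm / 100.0] * 3)
    motion = np.cumsum(steps, axis=0)
    motion -= motion[0]
    for frame, amp in motion_spikes:
        motion[int(frame):, 0] += float(amp)
    return ts, motion


def _clinical_draw(rng: np.random.Generator, group: str, separation_d: float) -> dict[str, float]:
    """Clinical scores; converters shift +d pooled-SD on every score."""
    out = {}
    for name, (mu, sd) in CLINICAL_BASELINE.items():
        if group == "HC":
            val = abs(rng.normal(0.0, 0.2))
        else:
            shift = separation_d * sd if group == "cPD_TD" else 0.0
            val = rng.normal(mu + shift, sd)
        val = max(0.0, float(val))
        if name == "HY":
            val = min(val, 5.0)
        out[name] = val
    return out


def simulate_cohort(
    blueprint: NetworkBlueprint,
    group_sizes: Mapping[str, int] = DEFAULT_GROUP_SIZES,
    planted_effect: Mapping[str, object] | None = None,
    clinical_separation: float = 0.0,
    seed: int | None = 0,
    *,
    return_motion: bool = False,
) -> tuple[list[SubjectSpec], list[VoxelTimeSeries], GroundTruth] | tuple[
        list[SubjectSpec], list[VoxelTimeSeries], list[np.ndarray], GroundTruth]:
    """Simulate a full cohort with an optional planted group effect.

    ``planted_effect`` is ``{"community": label, "multiplier": m, "group": g}``:
    subjects of group ``g`` have every edge of that community multiplied by
    ``m``.  ``clinical_separation`` is the Cohen-d shift of converter
    (``cPD_TD``) clinical scores relative to non-converters.  Ages and sexes
    are drawn iid from a common distribution for every group, so groups are
    balanced in distribution (cohorts are generated pre-matched).
    """
    for g, n in group_sizes.items():
        if n <= 0:
            raise ValueError(f"group size for {g} must be positive")
    eff_comm, eff_mult, eff_group = None, 1.0, None
    if planted_effect:
        eff_comm = str(planted_effect["community"])
        eff_mult = float(planted_effect["multiplier"])
        eff_group = str(planted_effect.get("group") or next(iter(group_sizes)))
        if eff_mult <= 0:
            raise ValueError("multiplier must be positive")
        if eff_comm not in blueprint.communities:
            raise ValueError(f"unknown community {eff_comm!r}")

    master = np.random.default_rng(np.random.SeedSequence([int(seed or 0), 0xC0

                                                           ]))
    specs: list[SubjectSpec] = []
    series: list[VoxelTimeSeries] = []
    motions: list[np.ndarray] = []
    idx = 0
    for group, n in group_sizes.items():
        for _ in range(n):
            rng = _subject_rng(seed, idx)
            age = float(np.clip(master.normal(61.0, 8.0), 35.0, 85.0))
            sex = "F" if master.random() < 0.5 else "M"
            effect_map = {}
            if eff_comm is not None and group == eff_group and eff_mult != 1.0:
                effect_map[eff_comm] = eff_mult
            sp = SubjectSpec(
                subject_id=f"sub-{idx:03d}", group=group, age=age, sex=sex,
                clinical=_clinical_draw(master, group, clinical_separation),
                effect_map=effect_map,
            )
            ts, motion = simulate_subject(blueprint, sp, rng)
            specs.append(sp)
            series.append(ts)
            motions.append(motion)
            idx += 1

    # ground truth = every community whose latent coupling TO THE SEED changes
    # under the effect map (the modulated community and any community whose
    # path to the seed crosses a modulated edge) — that is what seed-based
    # stepwise maps can legitimately detect
    planted_mask = np.zeros(blueprint.grid_shape, dtype=bool)
    if eff_comm is not None and eff_mult != 1.0:
        C0 = blueprint.latent_covariance()
        C1 = blueprint.latent_covariance({eff_comm: eff_mult})
        s_idx = blueprint.labels.index(blueprint.seed_community)
        changed = np.abs(C1[s_idx] - C0[s_idx]) > 1e-12
        coords = blueprint.voxel_coords()
        for ci, lab in enumerate(blueprint.labels):
            if changed[ci]:
                planted_mask[tuple(coords[blueprint.communities[lab]].T)] = True
    truth = GroundTruth(
        distances={k: int(v) for k, v in blueprint.graph_distances().items()},
        planted_mask=planted_mask,
        planted_community=eff_comm if eff_mult != 1.0 else None,
        planted_multiplier=eff_mult,
        clinical_separation_d=float(clinical_separation),
    )
    if return_motion:
        return specs, series, motions, truth
    return specs, series, truth


def simulate_task_subject(
    grid_shape: Sequence[int],
    active_mask: np.ndarray,
    task_regressor: np.ndarray,
    amplitude: float = 1.0,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator | None = 0,
    mask: np.ndarray | None = None,
) -> VoxelTimeSeries:
    """Block-design task run: ``amplitude * regressor`` added inside
    ``active_mask`` on top of white noise, for seed-mapping tests."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid_shape = tuple(int(g) for g in grid_shape)
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask, bool)
    active = np.asarray(active_mask, bool)[mask]
    n_t = len(task_regressor)
    data = noise_sd * rng.standard_normal((int(mask.sum()), n_t))
    data[active] += amplitude * np.asarray(task_regressor, float)
    return VoxelTimeSeries(data=data, mask=mask, tr_seconds=1.0)


# ---------------------------------------------------------------------------
# on-disk cohort layout (NIfTI + rp-dialect motion text + CSV + JSON)

def write_cohort(out_dir: str | Path, blueprint: NetworkBlueprint,
                 specs: list[SubjectSpec], series: list[VoxelTimeSeries],
                 motions: list[np.ndarray], truth: GroundTruth) -> Path:
    """Write a simulated cohort: one 4D NIfTI + rp_*.txt per subject, the
    analysis mask, the ground-truth mask, a cohort CSV and a truth JSON."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = np.diag([5.0, 5.0, 5.0, 1.0])  # 5 mm analysis grid
    nib.save(nib.Nifti1Image(blueprint.mask.astype(np.uint8), aff), out / "mask.nii")
    nib.save(nib.Nifti1Image(truth.planted_mask.astype(np.uint8), aff),
             out / "ground_truth_mask.nii")
    rows = []
    for sp, ts, motion in zip(specs, series, motions):
        img = nib.Nifti1Image(ts.to_4d(), aff)
        img.header.set_zooms((5.0, 5.0, 5.0, ts.tr_seconds))
        nib.save(img, out / f"{sp.subject_id}_bold.nii")
        np.savetxt(out / f"rp_{sp.subject_id}.txt", motion, fmt="%.8e")
        rows.append({"subject_id": sp.subject_id, "group": sp.group,
                     "age": sp.age, "sex": sp.sex, **sp.clinical})
    pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps({
        "distances": truth.distances,
        "planted_community": truth.planted_community,
        "planted_multiplier": truth.planted_multiplier,
        "clinical_separation_d": truth.clinical_separation_d,
    }, indent=2))
    return out
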