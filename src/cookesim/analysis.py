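"""Aggregate analysis: clustering, classification, sizes, CMC, ergodicity.

The pipeline mirrors standard practice for self-assembly trajectories:

1. single-linkage clustering of the *hydrophobic* beads at a distance
   cutoff (0.9 nm default), mapped up to molecules — restricting to tail
   beads avoids counting grazing contacts between aggregates;
2. clusters of fewer than 5 molecules are discarded; the remaining
   aggregates get an all-bead radius of gyration and are labelled disc
   when Rg >= 2.5 nm (micelle otherwise);
3. the aggregate *size* is the mean extent along the two leading principal
   axes of the member beads — a good proxy for the diameter of a sphere or
   a flat disc, which Rg is not;
4. free lipids (those outside every >= 5-molecule aggregate) give a
   concentration whose plateau across system size or total concentration
   estimates the critical micelle concentration;
5. the replica-to-replica mean square deviation of the aggregate count
   measures ergodicity, and a per-(system size, P/L) grid of phase labels
   with the 3x preferred-aggregate-size line forms the finite-size phase
   diagram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .engine import SystemState
from .sysbuild import concentration_mM_from_count
from .topology import Topology
from .units import Units, DEFAULT_UNITS

__all__ = [
    "Aggregate", "FrameAnalysis", "PhasePoint", "cluster_frame",
    "unwrap_cluster", "make_aggregates", "aggregate_size", "analyze_frame",
    "free_lipid_series", "cmc_from_size_scan", "cmc_from_concentration_scan",
    "ergodic_measure", "size_distribution_qq", "build_phase_diagram",
    "radius_of_gyration",
]

#: defaults for this coarse-grained model, in nm
DEFAULT_CLUSTER_CUTOFF_NM = 0.9
DEFAULT_RG_CUTOFF_NM = 2.5
MIN_AGGREGATE_MOLECULES = 5


@dataclass
class Aggregate:
    member_molecule_ids: frozenset
    n_lipids: int
    n_peptides: int
    rg: float                  # nm, all member beads
    size: float                # nm, mean top-2 principal-component range
    label: str                 # "micelle" | "disc"
    frame: int = 0

    @property
    def n_molecules(self) -> int:
        return self.n_lipids + self.n_peptides


@dataclass
class FrameAnalysis:
    aggregates: list[Aggregate]
    n_free_lipids: int
    free_lipid_concentration_mM: float
    frame_time: float = 0.0


@dataclass
class PhasePoint:
    n_lipids: int
    p_over_l: float
    phase: str                 # "micelle" | "disc" | "mixture"
    finite_size_flag: bool
    mean_lipids_per_aggregate: float


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------

def cluster_frame(state: SystemState, topology: Topology,
                  cutoff_nm: float = DEFAULT_CLUSTER_CUTOFF_NM,
                  units: Units = DEFAULT_UNITS) -> list[frozenset]:
    """Molecule clusters by single linkage over hydrophobic beads.

    Two molecules are linked when any of their hydrophobic beads are within
    the cutoff under minimum image; clusters are the connected components
    of that relation.  Every molecule appears in exactly one cluster
    (possibly a singleton).
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    cutoff = units.nm_to_sigma(cutoff_nm)
    mask = topology.hydrophobic_mask()
    mol_ids = topology.molecule_ids()
    n_mol = topology.n_molecules
    hydro_idx = np.flatnonzero(mask)
    if hydro_idx.size == 0:
        return [frozenset([m]) for m in range(n_mol)]
    box = state.box_edge
    pos = state.wrapped().positions[hydro_idx]
    # guard against coordinates landing exactly on the upper box face
    pos = np.where(pos >= box, pos - box, pos)
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    mol_of = mol_ids[hydro_idx]
    mi = mol_of[pairs[:, 0]] if len(pairs) else np.empty(0, dtype=int)
    mj = mol_of[pairs[:, 1]] if len(pairs) else np.empty(0, dtype=int)
    adj = coo_matrix((np.ones(len(mi)), (mi, mj)), shape=(n_mol, n_mol))
    n_comp, labels = connected_components(adj, directed=False)
    clusters: list[set] = [set() for _ in range(n_comp)]
    for mol, lab in enumerate(labels):
        clusters[lab].add(mol)
    return [frozenset(c) for c in clusters]


def unwrap_cluster(bead_idx: np.ndarray, state: SystemState,
                   topology: Topology) -> np.ndarray:
    """Unwrap a cluster's bead coordinates across periodic boundaries.

    Molecules are made whole relative to their first bead, then placed by
    a breadth-first walk of the molecule contact graph, shifting each
    molecule to the minimum image of an already-placed neighbor.  Geometry
    (Rg, PCA) on wrapped coordinates would be meaningless.
    """
    box = state.box_edge
    pos = state.wrapped().positions
    mol_ids = topology.molecule_ids()
    mols = sorted(set(mol_ids[bead_idx].tolist()))
    # make each molecule whole
    whole: dict[int, np.ndarray] = {}
    beads_of: dict[int, np.ndarray] = {}
    for m in mols:
        idx = np.flatnonzero(mol_ids == m)
        p = pos[idx].copy()
        d = p - p[0]
        d -= box * np.round(d / box)
        whole[m] = p[0] + d
        beads_of[m] = idx
    # greedy minimum-image placement: attach each pending molecule to the
    # nearest already-placed centroid, nearest-first (compact aggregates
    # never span half the box, so the local minimum image is correct)
    cents = np.array([whole[m].mean(axis=0) for m in mols])
    n_mol = len(mols)
    placed_cents = np.empty((n_mol, 3))
    placed_cents[0] = cents[0]
    shifts = np.zeros((n_mol, 3))
    done = np.zeros(n_mol, dtype=bool)
    done[0] = True
    n_done = 1
    while n_done < n_mol:
        pend = np.flatnonzero(~done)
        d = cents[pend][:, None, :] - placed_cents[None, :n_done, :]
        d -= box * np.round(d / box)
        dist = np.linalg.norm(d, axis=2)
        k_p, k_q = np.unravel_index(np.argmin(dist), dist.shape)
        m = pend[k_p]
        target = placed_cents[k_q] + d[k_p, k_q]
        shifts[m] = target - cents[m]
        placed_cents[n_done] = target
        done[m] = True
        n_done += 1
    lookup = {}
    for k, m in enumerate(mols):
        pts = whole[m] + shifts[k]
        for i, b in enumerate(beads_of[m]):
            lookup[int(b)] = pts[i]
    out = np.empty((len(bead_idx), 3))
    for k, b in enumerate(bead_idx):
        out[k] = lookup[int(b)]
    return out


def radius_of_gyration(coords: np.ndarray) -> float:
    """Mass-weighted (uniform masses) radius of gyration."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c ** 2).sum(axis=1).mean()))


def aggregate_size(coords: np.ndarray) -> float:
    """Mean extent along the two leading principal axes (unwrapped coords).

    Approximates the diameter of a spherical micelle or a flat disc.
    Degenerate (collinear) bead sets fall back to the available components
    with a warning.
    """
    c = coords - coords.mean(axis=0)
    cov = np.cov(c.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    ranges = []
    for k in order[:2]:
        if evals[k] <= 1e-12:
            warnings.warn("degenerate aggregate geometry; using available "
                          "principal components only")
            continue
        proj = c @ evecs[:, k]
        ranges.append(proj.max() - proj.min())
    if not ranges:
        return 0.0
    return float(np.mean(ranges))


def make_aggregates(clusters: list[frozenset], state: SystemState,
                    topology: Topology,
                    min_size: int = MIN_AGGREGATE_MOLECULES,
                    rg_cutoff_nm: float = DEFAULT_RG_CUTOFF_NM,
                    frame: int = 0,
                    units: Units = DEFAULT_UNITS) -> list[Aggregate]:
    """Aggregates (>= ``min_size`` molecules) with Rg, size and label.

    The label is "disc" iff the all-bead radius of gyration is at least
    ``rg_cutoff_nm``, "micelle" otherwise.
    """
    mol_ids = topology.molecule_ids()
    kinds = topology.bead_kinds()
    out = []
    for cluster in clusters:
        if len(cluster) < min_size:
            continue
        members = np.flatnonzero(np.isin(mol_ids, list(cluster)))
        coords = unwrap_cluster(members, state, topology)
        rg_nm = units.sigma_to_nm(radius_of_gyration(coords))
        size_nm = units.sigma_to_nm(aggregate_size(coords))
        mol_kind = {int(m): int(kinds[np.flatnonzero(mol_ids == m)[0]])
                    for m in cluster}
        n_pep = sum(1 for v in mol_kind.values() if v == 1)
        out.append(Aggregate(
            member_molecule_ids=frozenset(cluster),
            n_lipids=len(cluster) - n_pep,
            n_peptides=n_pep,
            rg=rg_nm,
            size=size_nm,
            label="disc" if rg_nm >= rg_cutoff_nm else "micelle",
            frame=frame))
    return out


def analyze_frame(state: SystemState, topology: Topology,
                  cutoff_nm: float = DEFAULT_CLUSTER_CUTOFF_NM,
                  rg_cutoff_nm: float = DEFAULT_RG_CUTOFF_NM,
                  min_size: int = MIN_AGGREGATE_MOLECULES,
                  frame: int = 0,
                  units: Units = DEFAULT_UNITS) -> FrameAnalysis:
    """Full per-frame analysis: aggregates plus free-lipid bookkeeping.

    Lipids in clusters below the aggregate threshold count as free; this
    is the complement of the reported aggregates, so every lipid is either
    free or in exactly one aggregate.
    """
    clusters = cluster_frame(state, topology, cutoff_nm, units)
    aggs = make_aggregates(clusters, state, topology, min_size,
                           rg_cutoff_nm, frame, units)
    kinds = topology.bead_kinds()
    mol_ids = topology.molecule_ids()
    lipid_mols = {int(m) for m in np.unique(mol_ids[kinds == 0])}
    in_agg = set()
    for a in aggs:
        in_agg |= a.member_molecule_ids
    n_free = len(lipid_mols - in_agg)
    conc = concentration_mM_from_count(n_free, state.box_edge, units)
    return FrameAnalysis(aggregates=aggs, n_free_lipids=n_free,
                         free_lipid_concentration_mM=conc,
                         frame_time=state.time)


# ----------------------------------------------------------------------
# CMC estimation
# ----------------------------------------------------------------------

@dataclass
class PlateauEstimate:
    mean_mM: float
    sd_mM: float
    series_mM: np.ndarray


def free_lipid_series(frames: list[FrameAnalysis],
                      window_fraction: float = 1.0 / 3.0
                      ) -> PlateauEstimate:
    """Free-lipid concentration time series and its equilibrated plateau.

    The plateau is the mean +- SD over the final ``window_fraction`` of the
    frames (default: last third).
    """
    if not frames:
        raise ValueError("no frames to analyze")
    series = np.array([f.free_lipid_concentration_mM for f in frames])
    n_win = max(1, int(round(len(series) * window_fraction)))
    window = series[-n_win:]
    return PlateauEstimate(float(window.mean()),
                           float(window.std(ddof=1)) if n_win > 1 else 0.0,
                           series)


@dataclass
class CMCEstimate:
    cmc_mM: float
    sd_mM: float
    curve: pd.DataFrame
    flags: dict = field(default_factory=dict)


def cmc_from_size_scan(plateaus_by_n: dict[int, PlateauEstimate],
                       n_largest: int = 1) -> CMCEstimate:
    """CMC from a system-size scan at fixed total concentration.

    Small systems underestimate the free-lipid concentration (a single
    aggregate soaks up most of the material), so the estimate is the
    plateau of the largest system(s); the full curve is returned for
    finite-size diagnosis and the smallest system is flagged as
    artificially low when it sits below the estimate.
    """
    if not plateaus_by_n:
        raise ValueError("no systems provided")
    ns = sorted(plateaus_by_n)
    curve = pd.DataFrame({
        "n_lipids": ns,
        "free_mM": [plateaus_by_n[n].mean_mM for n in ns],
        "sd_mM": [plateaus_by_n[n].sd_mM for n in ns],
    })
    top = ns[-n_largest:]
    est = float(np.mean([plateaus_by_n[n].mean_mM for n in top]))
    sd = float(np.mean([plateaus_by_n[n].sd_mM for n in top]))
    flags = {}
    smallest = plateaus_by_n[ns[0]]
    if len(ns) > 1 and smallest.mean_mM < est - sd:
        flags["artificially_low"] = [ns[0]]
    diffs = np.diff(curve["free_mM"].to_numpy())
    if np.any(diffs < -3 * max(sd, 1e-12)):
        flags["non_monotone"] = True
    return CMCEstimate(est, sd, curve, flags)


def cmc_from_concentration_scan(plateaus_by_conc: dict[float, PlateauEstimate],
                                aggregates_formed: dict[float, bool],
                                min_plateau_mM: float = 2.0) -> CMCEstimate:
    """CMC from a concentration scan at fixed system size.

    Below the CMC no stable aggregates form and free equals total; the CMC
    is the mean free-lipid concentration over the plateau region, i.e. the
    concentrations at/above ``min_plateau_mM`` where aggregates form.
    """
    concs = sorted(plateaus_by_conc)
    usable = [c for c in concs
              if c >= min_plateau_mM and aggregates_formed.get(c, False)]
    curve = pd.DataFrame({
        "total_mM": concs,
        "free_mM": [plateaus_by_conc[c].mean_mM for c in concs],
        "aggregates": [bool(aggregates_formed.get(c, False)) for c in concs],
    })
    if not usable:
        raise ValueError(
            "no plateau region: no concentrations >= "
            f"{min_plateau_mM} mM with stable aggregates "
            f"(usable candidates were {concs})")
    vals = np.array([plateaus_by_conc[c].mean_mM for c in usable])
    return CMCEstimate(float(vals.mean()),
                       float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                       curve, {"plateau_concentrations": usable})


# ----------------------------------------------------------------------
# ergodicity, distributions, phase diagram
# ----------------------------------------------------------------------

def ergodic_measure(counts: np.ndarray,
                    times: np.ndarray | None = None) -> np.ndarray:
    """Replica-pair mean square deviation of the aggregate count vs time.

    ``counts`` has shape (n_replicas, n_times).  d(t) is the average of
    [n_i(t) - n_j(t)]^2 over all replica pairs; decay toward a small
    plateau indicates the replicas have converged to the same macrostate.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need >= 2 replicas on a common time grid")
    r = counts.shape[0]
    d = np.zeros(counts.shape[1])
    n_pairs = 0
    for i in range(r):
        for j in range(i + 1, r):
            d += (counts[i] - counts[j]) ** 2
            n_pairs += 1
    return d / n_pairs


def replica_variance_measure(counts: np.ndarray) -> np.ndarray:
    """Across-replica variance of the aggregate count vs time (alternative)."""
    counts = np.asarray(counts, dtype=float)
    return counts.var(axis=0, ddof=0)


@dataclass
class QQResult:
    values: np.ndarray                 # pooled lipids-per-aggregate
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    mean: float
    sd: float
    theoretical_quantiles: np.ndarray
    order_statistics: np.ndarray
    upper_tail_deviation: float


def size_distribution_qq(aggregates: list[Aggregate],
                         n_bins: int = 20) -> QQResult:
    """Histogram + Gaussian QQ analysis of lipids per aggregate.

    The Gaussian reference uses the sample mean/SD (no truncation
    correction, so small samples can imply negative lipid counts — a known
    caveat of this diagnostic).  The upper-tail deviation is the largest
    excess of the upper-quartile order statistics over their Gaussian
    quantiles, in lipids; disc formation produces a long upper tail.
    """
    if len(aggregates) < 10:
        raise ValueError(
            f"need >= 10 aggregates for a meaningful distribution, "
            f"got {len(aggregates)}")
    values = np.sort(np.array([a.n_lipids for a in aggregates], dtype=float))
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    n = len(values)
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(probs, loc=mean, scale=sd)
    counts, edges = np.histogram(values, bins=n_bins)
    upper = slice(3 * n // 4, n)
    tail = float(np.max(values[upper] - theo[upper])) if n > 4 else 0.0
    return QQResult(values, counts, edges, mean, sd, theo, values, tail)


def build_phase_diagram(grid: dict[tuple[int, float], list[Aggregate]],
                        converged: dict[tuple[int, float], bool] | None = None
                        ) -> list[PhasePoint]:
    """Phase label per (n_lipids, P/L) point plus the finite-size flag.

    A point is "micelle" when every aggregate is a micelle, "disc" when all
    are discs, and "mixture" otherwise.  The finite-size boundary uses the
    3x heuristic: a point is flagged when its lipid count is below three
    times the preferred aggregate size, taken as the mean lipids per
    aggregate of the largest system at the same P/L.
    """
    converged = converged or {}
    # preferred aggregate size per P/L from the largest system
    preferred: dict[float, float] = {}
    for (n, pl), aggs in grid.items():
        if not aggs:
            continue
        best_n = max(nn for (nn, pp) in grid if pp == pl and grid[(nn, pp)])
        ref = grid[(best_n, pl)]
        preferred[pl] = float(np.mean([a.n_lipids for a in ref]))
    points = []
    for (n, pl), aggs in sorted(grid.items()):
        labels = {a.label for a in aggs}
        if not labels:
            phase = "none"
        elif labels == {"micelle"}:
            phase = "micelle"
        elif labels == {"disc"}:
            phase = "disc"
        else:
            phase = "mixture"
        mean_lip = float(np.mean([a.n_lipids for a in aggs])) if aggs else 0.0
        pref = preferred.get(pl, mean_lip)
        flag = n < 3.0 * pref
        if (n, pl) in converged and not converged[(n, pl)]:
            warnings.warn(f"phase point (n={n}, P/L={pl}) not converged; "
                          "included with warning")
        points.append(PhasePoint(n_lipids=n, p_over_l=pl, phase=phase,
                                 finite_size_flag=bool(flag),
                                 mean_lipids_per_aggregate=mean_lip))
    return points


def aggregates_to_frame(aggregates: list[Aggregate]) -> pd.DataFrame:
    """Tabular view of an aggregate list (one row per aggregate)."""
    return pd.DataFrame([{
        "frame": a.frame,
        "n_molecules": a.n_molecules,
        "n_lipids": a.n_lipids,
        "n_peptides": a.n_peptides,
        "rg_nm": a.rg,
        "size_nm": a.size,
        "label": a.label,
    } for a in aggregates])
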