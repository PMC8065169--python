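"""Per-time-slot ecoregionalization and fragmentation/strength summaries.

``run_slot`` drives one window end to end: anomalies -> domains -> network ->
KE summaries.  Across a slot sweep, ``fragmentation_vs_ke`` and
``strength_vs_ke`` correlate the domain count and mean domain strength with
the slot-mean kinetic energy, optionally per basin partition (e.g. an
east/west split at a meridian).  ``compare_networks`` reports how the edges
of the domain containing a reference point change between two slots.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .grid import GriddedField, TimeSlot
from . import preprocess
from .domains import DomainSet, identify_domains, delta_from_alpha, DEFAULT_DELTA, DEFAULT_K
from .network import FunctionalNetwork, domain_signals, infer_network
from . import kefronts

__all__ = [
    "PipelineConfig", "BasinPartition", "SlotResult",
    "run_slot", "run_sweep", "fragmentation_vs_ke", "strength_vs_ke",
    "compare_networks",
]

log = logging.getLogger("ecoregions")

# alpha per slot length, used when delta is derived rather than fixed:
# 1e-3 for the 4-year validation window, 2e-5 for 7-year slots,
# 6e-5 for 6-year and 3e-6 for 8-year slots.
ALPHA_BY_DELTA_YEARS = {4: 1e-3, 6: 6e-5, 7: 2e-5, 8: 3e-6}


@dataclass(frozen=True)
class PipelineConfig:
    K: int = DEFAULT_K
    delta: float | None = DEFAULT_DELTA   # fixed-delta mode (default)
    use_alpha_table: bool = False         # derive delta from ALPHA_BY_DELTA_YEARS
    tau_max: int = 12
    level: float = 0.03
    dist: str = "t"
    lag_correction: str = "none"
    detrend_scope: str = "full"           # "full" record or per-"slot"
    percentile: float = 50.0
    kmeans_k: int = 4
    seed: int = 0
    split_lon: float | None = None        # east/west partition meridian

    def resolve_delta(self, delta_years: int, T: int) -> tuple:
        """(delta, alpha) for a slot of the given length."""
        if self.use_alpha_table:
            alpha = ALPHA_BY_DELTA_YEARS.get(delta_years)
            if alpha is None:
                raise ValueError(
                    f"no alpha configured for {delta_years}-year slots "
                    f"(have {sorted(ALPHA_BY_DELTA_YEARS)})"
                )
            return delta_from_alpha(alpha, T), alpha
        if self.delta is None:
            raise ValueError("either delta or use_alpha_table must be set")
        return self.delta, None


@dataclass(frozen=True)
class BasinPartition:
    """Named disjoint cell subsets of the ocean (boolean masks)."""
    members: dict

    @classmethod
    def split_at_meridian(cls, field: GriddedField, lon_split: float) -> "BasinPartition":
        west = field.mask & (field.lon[None, :] < lon_split)
        east = field.mask & (field.lon[None, :] >= lon_split)
        return cls(members={"west": west, "east": east})

    @classmethod
    def whole(cls, field: GriddedField) -> "BasinPartition":
        return cls(members={"basin": field.mask.copy()})


@dataclass
class SlotResult:
    slot: TimeSlot
    domain_set: DomainSet
    network: FunctionalNetwork
    mean_ke: float                 # slot/basin mean, m2/s2
    mean_ke_map: np.ndarray        # slot time-mean KE per cell
    max_cluster_pixels: int
    cluster_counts: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    mask: np.ndarray
    front_counts: np.ndarray | None = None

    @property
    def n_domains(self) -> int:
        return len(self.domain_set)

    def label_map(self) -> np.ndarray:
        return self.domain_set.label_map()

    def strength_map(self) -> np.ndarray:
        """Per-cell strength of the covering domain; NaN on background/land."""
        out = np.full(self.domain_set.shape, np.nan)
        for d in self.domain_set.domains:
            s = self.network.nodes.get(d.id, 0.0)
            for c in d.cells:
                out[c] = s
        return out


def run_slot(
    sst: GriddedField,
    u: GriddedField,
    v: GriddedField,
    slot: TimeSlot,
    cfg: PipelineConfig = PipelineConfig(),
    ke_ref_threshold: float | None = None,
) -> SlotResult:
    """One time slot end to end; deterministic given config and seed."""
    if not sst.mask.any():
        raise ValueError(f"slot {slot}: field has no ocean cells")
    try:
        if cfg.detrend_scope == "full":
            anoms = preprocess.slice_field(preprocess.anomalies(sst), slot)
        elif cfg.detrend_scope == "slot":
            anoms = preprocess.anomalies(preprocess.slice_field(sst, slot))
        else:
            raise ValueError("detrend_scope must be 'full' or 'slot'")
        delta, alpha = cfg.resolve_delta(slot.delta, anoms.n_time)
        ds = identify_domains(anoms, K=cfg.K, delta=delta)
        if alpha is not None:
            ds = replace(ds, alpha=alpha)
        sigs = domain_signals(ds, anoms)
        net = infer_network(
            sigs, tau_max=cfg.tau_max, level=cfg.level, dist=cfg.dist,
            lag_correction=cfg.lag_correction,
        )
        ke = preprocess.kinetic_energy(
            preprocess.slice_field(u, slot), preprocess.slice_field(v, slot)
        )
        mean_ke_map = np.full(ke.mask.shape, np.nan)
        mean_ke_map[ke.mask] = ke.values[:, ke.mask].mean(axis=0)
        mean_ke = float(np.mean(mean_ke_map[ke.mask]))
        _, counts, _ = kefronts.kmeans_segment(
            mean_ke_map, ke.mask, k=cfg.kmeans_k, seed=cfg.seed
        )
        front_counts = None
        if ke_ref_threshold is not None:
            front_counts = kefronts.front_occurrence(ke, ke_ref_threshold)
    except Exception as exc:
        raise RuntimeError(f"slot {slot}: {exc}") from exc
    log.info(
        "slot %s: %d domains, %d edges, mean KE %.3g (delta=%.3f, K=%d, seed=%d)",
        slot, len(ds), len(net.edges), mean_ke, delta, cfg.K, cfg.seed,
    )
    return SlotResult(
        slot=slot, domain_set=ds, network=net, mean_ke=mean_ke,
        mean_ke_map=mean_ke_map, max_cluster_pixels=int(counts[-1]),
        cluster_counts=counts, lat=sst.lat.copy(), lon=sst.lon.copy(),
        mask=sst.mask.copy(), front_counts=front_counts,
    )


def run_sweep(sst, u, v, slots, cfg: PipelineConfig = PipelineConfig()) -> list:
    """Run every slot; the KE front threshold is fixed from the full record."""
    ke_full = preprocess.kinetic_energy(u, v)
    thr = kefronts.ke_threshold(ke_full, cfg.percentile)
    return [run_slot(sst, u, v, s, cfg, ke_ref_threshold=thr) for s in slots]


# -- cross-slot summaries ---------------------------------------------------

def _member_domain_count(result: SlotResult, member_mask: np.ndarray) -> int:
    """Domains assigned to the member holding the majority of their cells."""
    n = 0
    for d in result.domain_set.domains:
        inside = sum(1 for c in d.cells if member_mask[c])
        if inside > len(d.cells) / 2:
            n += 1
    return n


def _pearson(x, y) -> float | None:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None  # undefined for a constant series
    return float(stats.pearsonr(x, y)[0])


def fragmentation_vs_ke(results, partition: BasinPartition | None = None) -> dict:
    """Pearson correlation of domain count vs slot-mean KE, per partition member.

    Returns {member: cc or None}; None flags an undefined (constant-series)
    correlation.  Requires at least 3 slots.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 slot results")
    if partition is None:
        mask = np.ones(results[0].domain_set.shape, dtype=bool)
        partition = BasinPartition(members={"basin": mask})
    out = {}
    for name, mm in partition.members.items():
        counts = [_member_domain_count(r, mm) for r in results]
        kes = [float(np.nanmean(r.mean_ke_map[mm])) for r in results]
        out[name] = _pearson(counts, kes)
    return out


def strength_vs_ke(results, partition: BasinPartition | None = None) -> dict:
    """Pearson correlation of spatially averaged domain strength vs mean KE."""
    if len(results) < 3:
        raise ValueError("need at least 3 slot results")
    if partition is None:
        mask = np.ones(results[0].domain_set.shape, dtype=bool)
        partition = BasinPartition(members={"basin": mask})
    out = {}
    for name, mm in partition.members.items():
        strengths = []
        kes = []
        for r in results:
            smap = r.strength_map()
            vals = smap[mm & np.isfinite(smap)]
            strengths.append(float(vals.mean()) if vals.size else np.nan)
            kes.append(float(np.nanmean(r.mean_ke_map[mm])))
        if np.any(~np.isfinite(strengths)):
            out[name] = None
            continue
        out[name] = _pearson(strengths, kes)
    return out


# -- network comparison -----------------------------------------------------

def _match_domains(ds1: DomainSet, ds2: DomainSet, min_jaccard: float = 0.3) -> dict:
    """Map domain id in ds1 -> best-overlapping domain id in ds2 (or None)."""
    cells2 = {d.id: set(d.cells) for d in ds2.domains}
    mapping = {}
    for d in ds1.domains:
        s1 = set(d.cells)
        best, best_j = None, min_jaccard
        for id2, s2 in cells2.items():
            j = len(s1 & s2) / len(s1 | s2)
            if j >= best_j:
                best, best_j = id2, j
        mapping[d.id] = best
    return mapping


def compare_networks(
    result1: SlotResult, result2: SlotResult, lat: float, lon: float,
    min_jaccard: float = 0.3, weight_rtol: float = 1e-9,
):
    """Edge diff for the domain containing (lat, lon), across two slot results.

    Counterpart domains are matched by spatial overlap (Jaccard >= 0.3).
    Returns a dict with the focus ids and lists of lost / gained / changed
    edges, each referenced by the counterpart domain on the far end.
    """
    ds1, ds2 = result1.domain_set, result2.domain_set
    if ds1.shape != ds2.shape:
        raise ValueError("results are not on the same grid")
    ilat = int(np.argmin(np.abs(result1.lat - lat)))
    ilon = int(np.argmin(np.abs(result1.lon - lon)))
    if not result1.mask[ilat, ilon]:
        raise ValueError(f"point ({lat}, {lon}) falls on land")
    focus1 = ds1.locate(ilat, ilon)
    focus2 = ds2.locate(ilat, ilon)
    if focus1 is None or focus2 is None:
        raise ValueError(f"point ({lat}, {lon}) is background in one of the results")

    mapping = _match_domains(ds1, ds2, min_jaccard)
    if mapping.get(focus1.id) != focus2.id:
        # the point itself pins the focus correspondence
        mapping[focus1.id] = focus2.id

    edges1 = {e.A if e.B == focus1.id else e.B: e
              for e in result1.network.edges if focus1.id in (e.A, e.B)}
    edges2 = {e.A if e.B == focus2.id else e.B: e
              for e in result2.network.edges if focus2.id in (e.A, e.B)}
    inv = {v: k for k, v in mapping.items() if v is not None}

    lost, gained, changed = [], [], []
    for other1, e1 in edges1.items():
        other2 = mapping.get(other1)
        e2 = edges2.get(other2) if other2 is not None else None
        if e2 is None:
            lost.append({"other": other1, "w": e1.w, "r": e1.r,
                         "direction": e1.direction})
        elif not np.isclose(e1.w, e2.w, rtol=weight_rtol, atol=0.0) or \
                e1.direction != e2.direction:
            changed.append({"other": other1, "counterpart": other2,
                            "w_before": e1.w, "w_after": e2.w,
                            "direction_before": e1.direction,
                            "direction_after": e2.direction})
    for other2, e2 in edges2.items():
        if inv.get(other2) not in edges1:
            gained.append({"other": other2, "w": e2.w, "r": e2.r,
                           "direction": e2.direction})
    return {
        "focus_1": focus1.id, "focus_2": focus2.id, "mapping": mapping,
        "lost": lost, "gained": gained, "changed": changed,
    }
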