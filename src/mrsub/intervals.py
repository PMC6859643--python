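"""Concestor intervals and tissue enrichment.

A site whose no-substitution probability is below threshold is assigned to
the smallest interval between two concestor times that contains its
``[t - z*sigma, t + z*sigma]`` confidence interval (clipped to the lineage
extent, with closed containment at the interval bounds so leaf-to-root
assignments remain possible).  Region sets are then tested for
tissue-by-interval enrichment with the hypergeometric upper tail, ranked
by the standardised deviate (Z-score).
"""

from __future__ import annotations

import bisect
import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .engine import SiteEstimates
from .tree import TargetLineage

__all__ = [
    "ConcestorTable",
    "IntervalAssignment",
    "EnrichmentRecord",
    "DEFAULT_CONCESTORS",
    "assign_interval",
    "reduce_concestors",
    "concestor_table_from_lineage",
    "map_sites_to_regions",
    "hypergeometric_enrichment",
]


@dataclasses.dataclass(frozen=True)
class ConcestorTable:
    """Named ancestor nodes on the target lineage with times from present."""

    names: tuple
    times: np.ndarray  # substitutions/site, strictly increasing, times[0] == 0

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if len(self.names) != len(times) or len(times) < 2:
            raise ValueError("need matching names/times with at least two rows")
        if times[0] != 0:
            raise ValueError("first concestor must be at time 0 (the target)")
        if np.any(np.diff(times) <= 0):
            raise ValueError("concestor times must be strictly increasing")

    @property
    def tbar(self) -> float:
        return float(self.times[-1])


#: human-lineage reduced concestor set used in the enrichment analyses
DEFAULT_CONCESTORS = ConcestorTable(
    names=(
        "Homo",
        "Hominoidea",
        "Euarchontoglires",
        "Eutheria",
        "Mammalia",
        "Amniota",
        "Tetrapoda",
        "Vertebrata",
    ),
    times=np.array([0.0, 0.026, 0.17, 0.22, 0.55, 0.69, 0.80, 1.1]),
)


@dataclasses.dataclass(frozen=True)
class IntervalAssignment:
    late: str | None
    early: str | None
    reason: str | None = None  # 'q-fail' | 'skipped' when unassigned

    @property
    def assigned(self) -> bool:
        return self.late is not None

    @property
    def label(self) -> str:
        if not self.assigned:
            return f"unassigned({self.reason})"
        return f"{self.late}-{self.early}"


def assign_interval(
    est: SiteEstimates,
    table: ConcestorTable,
    q_threshold: float = 0.01,
    z: float = 2.0,
) -> IntervalAssignment:
    """Smallest concestor interval containing ``[t - z s, t + z s]``.

    The confidence interval is clipped to ``[0, tbar]`` first; containment
    allows equality at the concestor times, so a site whose interval spans
    everything is assigned leaf-to-root rather than dropped.
    """
    if est.skipped:
        return IntervalAssignment(None, None, "skipped")
    if not est.q < q_threshold:
        return IntervalAssignment(None, None, "q-fail")
    lo = max(0.0, est.t_mrs - z * est.sigma)
    hi = min(table.tbar, est.t_mrs + z * est.sigma)
    times = table.times
    late_candidates = np.flatnonzero(times <= lo + 1e-12)
    early_candidates = np.flatnonzero(times >= hi - 1e-12)
    i = int(late_candidates[-1])  # latest concestor not after lo
    j = int(early_candidates[0])  # earliest concestor not before hi
    if j <= i:
        j = i + 1
    return IntervalAssignment(table.names[i], table.names[j])


def reduce_concestors(full: ConcestorTable, grouping: Mapping[str, str]) -> ConcestorTable:
    """Collapse consecutive concestors into named groups.

    ``grouping`` maps every full concestor name to a reduced name; groups
    must be contiguous and order-preserving.  Each reduced concestor keeps
    the time of its most recent (first) member — no averaging.
    """
    missing = [n for n in full.names if n not in grouping]
    if missing:
        raise ValueError(f"grouping misses concestors: {missing}")
    names: list[str] = []
    times: list[float] = []
    for name, t in zip(full.names, full.times):
        red = grouping[name]
        if names and red == names[-1]:
            continue
        if red in names:
            raise ValueError(f"grouping is not order-preserving at {name!r}")
        names.append(red)
        times.append(float(t))
    return ConcestorTable(names=tuple(names), times=np.array(times))


def concestor_table_from_lineage(lineage: TargetLineage, names: Sequence[str] | None = None) -> ConcestorTable:
    """Concestor times straight from a target lineage (c_0 .. c_M)."""
    if names is None:
        names = [f"c{k}" for k in range(lineage.M + 1)]
    return ConcestorTable(names=tuple(names), times=lineage.taus.copy())


def map_sites_to_regions(
    sites: Sequence[tuple],
    regions: Sequence[tuple],
) -> dict:
    """Assign sites ``(chrom, pos)`` to 0-based half-open BED-like regions
    ``(chrom, start, end, name)``; a site joins every overlapping region.

    Returns ``{region_name: [site indices]}`` (insertion order deterministic
    in region order, site lists sorted)."""
    by_chrom: dict[str, list] = {}
    for i, (chrom, pos) in enumerate(sites):
        by_chrom.setdefault(chrom, []).append((int(pos), i))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    out: dict[str, list] = {}
    for region in regions:
        chrom, start, end = region[0], int(region[1]), int(region[2])
        name = region[3] if len(region) > 3 else f"{chrom}:{start}-{end}"
        entries = by_chrom.get(chrom, [])
        positions = [p for p, _ in entries]
        a = bisect.bisect_left(positions, start)
        b = bisect.bisect_left(positions, end)
        hits = sorted(entries[k][1] for k in range(a, b))
        out.setdefault(name, [])
        out[name] = sorted(set(out[name]) | set(hits))
    return out


@dataclasses.dataclass(frozen=True)
class EnrichmentRecord:
    tissue: str
    interval: str
    universe: int
    tissue_count: int
    interval_count: int
    observed: int
    expected: float
    enrichment: float
    p_value: float
    z_score: float


def hypergeometric_enrichment(
    universe: Iterable,
    tissue_sets: Mapping[str, Iterable],
    interval_sets: Mapping[str, Iterable],
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric test for every tissue x interval pair.

    With universe size N, K tissue-labelled elements and n
    interval-containing elements, the overlap X is tested with
    ``P(X >= observed)``; the Z-score is the standardised hypergeometric
    deviate.  Records are sorted by tissue, then descending Z.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    N = len(uni)
    records = []
    for tissue, tset in tissue_sets.items():
        K_set = set(tset) & uni
        K = len(K_set)
        for interval, iset in interval_sets.items():
            n_set = set(iset) & uni
            n = len(n_set)
            obs = len(K_set & n_set)
            expected = n * K / N
            p = float(hypergeom.sf(obs - 1, N, K, n)) if obs > 0 else 1.0
            var = n * K * (N - K) * (N - n) / (N * N * (N - 1)) if N > 1 else 0.0
            z = (obs - expected) / np.sqrt(var) if var > 0 else 0.0
            records.append(
                EnrichmentRecord(
                    tissue=tissue,
                    interval=interval,
                    universe=N,
                    tissue_count=K,
                    interval_count=n,
                    observed=obs,
                    expected=expected,
                    enrichment=(obs / expected) if expected > 0 else np.nan,
                    p_value=p,
                    z_score=float(z),
                )
            )
    records.sort(key=lambda r: (r.tissue, -r.z_score))
    return records


def enrichment_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Tissue": [r.tissue for r in records],
            "Interval": [r.interval for r in records],
            "Z": [r.z_score for r in records],
            "-log10(p)": [-np.log10(max(r.p_value, 1e-300)) for r in records],
            "Enrichment": [r.enrichment for r in records],
            "Observed": [r.observed for r in records],
        }
    )
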