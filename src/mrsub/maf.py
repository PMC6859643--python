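"""Readers and writers: MAF alignment columns, BED regions, site tables.

MAF blocks are parsed with Bio.AlignIO; rows are keyed by the species
prefix of the ``src`` field (``hg38.chr1`` -> ``hg38``).  Coordinates are
0-based half-open internally; reverse-strand target rows are converted to
forward-strand positions using the MAF ``srcSize`` field.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .engine import SiteEstimates
from .rates import NUC_INDEX

__all__ = [
    "MafColumn",
    "read_maf_columns",
    "write_maf",
    "read_bed",
    "sample_columns",
    "write_site_table",
]


class MafError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class MafColumn:
    """One alignment column anchored on the target species."""

    chrom: str
    pos: int            # 0-based position on the target genome
    column: dict        # species -> symbol
    skipped: bool       # target symbol is a gap/ambiguity


def _species_of(src: str) -> str:
    return src.split(".", 1)[0]


def read_maf_columns(
    path,
    target: str,
    species: Sequence[str] | None = None,
) -> Iterator[MafColumn]:
    """Stream per-position columns from a MAF file.

    Blocks without the target species are skipped entirely.  Positions at
    which the target carries a gap or an ambiguous character are yielded
    with ``skipped=True`` so callers can log them.
    """
    keep = set(species) if species is not None else None
    with open(path) as handle:
        try:
            blocks = list(AlignIO.parse(handle, "maf"))
        except Exception as exc:  # malformed block
            raise MafError(f"malformed MAF file {path}: {exc}") from exc
    for block in blocks:
        rows = {}
        anchor = None
        for rec in block:
            sp = _species_of(rec.id)
            if keep is not None and sp != target and sp not in keep:
                continue
            rows[sp] = str(rec.seq).upper()
            if sp == target:
                anchor = rec
        if anchor is None:
            continue
        text = rows[target]
        start = int(anchor.annotations["start"])
        size = int(anchor.annotations["size"])
        strand = int(anchor.annotations.get("strand", 1))
        src_size = int(anchor.annotations.get("srcSize", 0))
        chrom = anchor.id.split(".", 1)[1] if "." in anchor.id else anchor.id
        offset = 0
        for i, target_sym in enumerate(text):
            is_gap = target_sym not in NUC_INDEX
            if strand >= 0:
                pos = start + offset
            else:
                pos = src_size - 1 - (start + offset)
            column = {sp: seq[i] for sp, seq in rows.items()}
            yield MafColumn(chrom=chrom, pos=pos, column=column, skipped=is_gap)
            if not is_gap:
                offset += 1
        if offset != size:
            raise MafError(
                f"block for {anchor.id} declares size {size} but has {offset} bases"
            )


def write_maf(
    path,
    columns: Sequence[Mapping[str, str]],
    species: Sequence[str],
    target: str,
    chrom: str = "chr1",
    start: int = 0,
) -> None:
    """Write columns as a single forward-strand MAF block (one row per
    species; missing symbols become gaps)."""
    seqs = {
        sp: "".join((col.get(sp) or "-") for col in columns) for sp in species
    }
    n = len(columns)
    width = max(len(f"{sp}.{chrom}") for sp in species) + 2
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        fh.write("a score=0.0\n")
        for sp in species:
            seq = seqs[sp]
            size = sum(c in NUC_INDEX for c in seq.upper())
            src = f"{sp}.{chrom}" if sp == target else f"{sp}.scaf"
            fh.write(
                f"s {src:<{width}} {start if sp == target else 0} {size} + "
                f"{start + n if sp == target else size} {seq}\n"
            )
        fh.write("\n")


def read_bed(path) -> list[tuple]:
    """Parse BED3+ into ``(chrom, start, end, name)`` tuples."""
    regions = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise MafError(f"{path}:{lineno}: BED line needs >= 3 fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise MafError(f"{path}:{lineno}: non-integer coordinates") from exc
        if end < start:
            raise MafError(f"{path}:{lineno}: end < start")
        name = fields[3] if len(fields) > 3 else f"{fields[0]}:{start}-{end}"
        regions.append((fields[0], start, end, name))
    return regions


def sample_columns(
    stream: Iterable[MafColumn],
    n: int,
    seed: int | None = None,
    regions: Sequence[tuple] | None = None,
) -> list[MafColumn]:
    """Reservoir-sample ``n`` scoreable columns from a stream.

    Optionally restrict to BED regions (0-based half-open).  Deterministic
    for a fixed seed and stream order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    wanted = None
    if regions is not None:
        wanted = {}
        for chrom, start, end, _ in regions:
            wanted.setdefault(chrom, []).append((start, end))
    reservoir: list[MafColumn] = []
    seen = 0
    for col in stream:
        if col.skipped:
            continue
        if wanted is not None:
            spans = wanted.get(col.chrom, [])
            if not any(s <= col.pos < e for s, e in spans):
                continue
        seen += 1
        if len(reservoir) < n:
            reservoir.append(col)
        else:
            j = int(rng.integers(seen))
            if j < n:
                reservoir[j] = col
    if seen == 0:
        raise MafError("no scoreable columns in stream")
    return reservoir


def write_site_table(
    path,
    sites: Sequence[tuple],
) -> None:
    """TSV of per-site estimates: rows are
    ``(chrom, pos, base, estimates, optional assignment label)``."""
    rows = []
    for entry in sites:
        chrom, pos, est = entry[0], entry[1], entry[2]
        label = entry[3] if len(entry) > 3 else ""
        if est.skipped:
            continue
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "base": est.target_base,
                "t_mrs": est.t_mrs,
                "sigma": est.sigma,
                "q": est.q,
                "log_z": est.log_z,
                "interval": label,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
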