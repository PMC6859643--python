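"""Synthetic fixtures: random trees and complete offline test bundles.

Everything the command-line interface consumes (tree, model file, MAF
alignment, truth table, BED regions, tissue labels) can be generated here
from a seed, so the whole toolchain runs without any external downloads.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import maf as mafio
from .rates import RateModel, default_model, write_model
from .simulate import apply_gap_mask, forward_simulate, synthetic_mask_templates
from .tree import PhyloTree, write_newick

__all__ = ["make_random_tree", "make_ladder_tree", "FixtureSpec", "generate_fixtures"]


def make_random_tree(
    n_taxa: int,
    depth: float = 1.0,
    seed: int | None = None,
    prefix: str = "sp",
) -> PhyloTree:
    """Random ultrametric binary tree with ``n_taxa`` leaves and root at
    ``depth`` (so every leaf-to-root path has length ``depth``).

    Coalescent-style construction: lineages merge in random pairs at
    sorted random heights.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    heights = np.sort(rng.uniform(0.05 * depth, depth, n_taxa - 1))
    heights[-1] = depth

    parent = []
    children = []
    lengths = []
    names = []
    node_height = []

    def new_node(name, height):
        parent.append(-1)
        children.append([])
        lengths.append(0.0)
        names.append(name)
        node_height.append(height)
        return len(parent) - 1

    active = [new_node(f"{prefix}{i+1}", 0.0) for i in range(n_taxa)]
    for h in heights:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        p = new_node(None, float(h))
        for kid in (a, b):
            parent[kid] = p
            lengths[kid] = float(h - node_height[kid])
            children[p].append(kid)
        active.append(p)

    return PhyloTree(
        parent=np.array(parent, dtype=int),
        children=tuple(tuple(c) for c in children),
        lengths=np.array(lengths),
        names=tuple(names),
    )


def make_ladder_tree(
    n_taxa: int,
    depth: float = 1.1,
    first_split: float = 0.012,
    prefix: str = "sp",
) -> PhyloTree:
    """Caterpillar tree with geometrically spaced split heights.

    The first leaf sees every internal node on its lineage (``n_taxa - 1``
    ancestors), with many recent splits — the shape a deep species tree
    presents to one of its leaves, which is what gives per-site time
    estimates their resolution near the present.
    """
    if n_taxa < 3:
        raise ValueError("need at least three taxa")
    heights = np.geomspace(first_split, depth, n_taxa - 1)
    nwk = f"{prefix}1:{heights[0]:.10g}"
    for k in range(1, n_taxa):
        h = heights[k - 1]
        if k < n_taxa - 1:
            nwk = f"({nwk},{prefix}{k+1}:{h:.10g}):{heights[k] - h:.10g}"
        else:
            nwk = f"({nwk},{prefix}{k+1}:{h:.10g});"
    return PhyloTree.from_newick(nwk)


@dataclasses.dataclass
class FixtureSpec:
    n_taxa: int = 10
    depth: float = 1.0
    n_sites: int = 200
    gap_probability: float = 0.5  # overall strength of the synthetic masks
    target: str = "sp1"
    chrom: str = "chr1"
    model: RateModel | None = None


def generate_fixtures(spec: FixtureSpec, outdir, seed: int = 0) -> dict:
    """Write a complete fixture bundle; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    model = spec.model or default_model().normalized()
    tree = make_random_tree(spec.n_taxa, spec.depth, seed=seed)
    species = tree.leaf_names

    sims = forward_simulate(tree, model, spec.target, spec.n_sites, seed=int(rng.integers(2**31)))
    if spec.gap_probability > 0:
        templates = synthetic_mask_templates(
            tree,
            spec.target,
            n_templates=max(32, spec.n_sites // 4),
            seed=int(rng.integers(2**31)),
            max_prob=spec.gap_probability,
        )
        sims = apply_gap_mask(sims, templates, spec.target, seed=int(rng.integers(2**31)))

    paths = {
        "tree": outdir / "tree.nwk",
        "model": outdir / "model.txt",
        "maf": outdir / "alignment.maf",
        "truth": outdir / "truth.tsv",
        "bed": outdir / "regions.bed",
        "tissues": outdir / "tissues.tsv",
    }
    write_newick(tree, paths["tree"])
    write_model(model, paths["model"])
    mafio.write_maf(
        paths["maf"],
        [s.column for s in sims],
        species=species,
        target=spec.target,
        chrom=spec.chrom,
    )
    pd.DataFrame(
        {
            "chrom": spec.chrom,
            "pos": np.arange(spec.n_sites),
            "true_t": [s.true_t for s in sims],
            "true_q": [s.true_q for s in sims],
        }
    ).to_csv(paths["truth"], sep="\t", index=False)

    # a handful of non-overlapping regions with round-robin tissue labels
    n_regions = max(4, spec.n_sites // 25)
    bounds = np.sort(rng.choice(spec.n_sites, size=2 * n_regions, replace=False))
    tissues = ["brain", "liver", "heart", "eye"]
    with open(paths["bed"], "w") as bed, open(paths["tissues"], "w") as tis:
        tis.write("region\ttissue\n")
        for r in range(n_regions):
            start, end = int(bounds[2 * r]), int(bounds[2 * r + 1]) + 1
            name = f"enh{r+1}"
            bed.write(f"{spec.chrom}\t{start}\t{end}\t{name}\n")
            tis.write(f"{name}\t{tissues[r % len(tissues)]}\n")
    return paths
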