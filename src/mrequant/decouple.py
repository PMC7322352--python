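"""Decoupling: split an MRE set into its mRNA and microRNA members.

An MRE is the physical interaction site of a (gene, microRNA family) pair,
so a selected MRE set decouples into the unique gene list, the unique
microRNA list, the pair table, and a per-gene multiplicity (how many
distinct selected MREs each gene carries).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

KEY_SEP = "|"


def parse_mre_key(key) -> tuple[str, str]:
    """Accepts a (gene, family) tuple or a 'gene|family' string."""
    if isinstance(key, tuple) and len(key) == 2:
        gene, fam = key
    elif isinstance(key, str) and key.count(KEY_SEP) == 1:
        gene, fam = key.split(KEY_SEP)
    else:
        raise ValueError(f"malformed MRE key: {key!r}")
    if not gene or not fam:
        raise ValueError(f"malformed MRE key: {key!r}")
    return str(gene), str(fam)


@dataclass
class DecoupledSets:
    """Unique gene and microRNA lists plus the pair table, lexicographically ordered."""

    genes: list[str]
    mirnas: list[str]
    pairs: list[tuple[str, str]]
    multiplicity: dict[str, int]

    def write_tsv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        pd.DataFrame({"gene_id": self.genes}).to_csv(outdir / "genes.tsv", sep="\t", index=False)
        pd.DataFrame({"family_id": self.mirnas}).to_csv(outdir / "mirnas.tsv", sep="\t", index=False)
        pd.DataFrame(self.pairs, columns=["gene_id", "family_id"]).to_csv(
            outdir / "pairs.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            sorted(self.multiplicity.items()), columns=["gene_id", "n_mres"]
        ).to_csv(outdir / "multiplicity.tsv", sep="\t", index=False)


def decouple(mre_set: Iterable) -> DecoupledSets:
    """Unique genes, unique microRNAs, pairs, and per-gene MRE multiplicity."""
    pairs = sorted({parse_mre_key(k) for k in mre_set})
    genes = sorted({g for g, _ in pairs})
    mirnas = sorted({f for _, f in pairs})
    mult: dict[str, int] = {g: 0 for g in genes}
    for g, _ in pairs:
        mult[g] += 1
    return DecoupledSets(genes, mirnas, pairs, mult)


def multiplicity_summary(sets: DecoupledSets) -> int:
    """Number of genes carrying two or more selected MREs."""
    return sum(1 for n in sets.multiplicity.values() if n >= 2)
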