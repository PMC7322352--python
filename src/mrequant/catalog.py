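"""MRE catalog construction.

A microRNA represses an mRNA through short complementary sites — microRNA
response elements (MREs) — in the mRNA's 3'UTR. Canonical sites pair with the
microRNA *seed region* (nucleotides 2-8) and come in four types, named by the
extent of Watson-Crick pairing:

* ``8mer``    — seed match (positions 2-8) plus an ``A`` opposite position 1
* ``7mer-m8`` — seed match including position 8
* ``7mer-A1`` — match to positions 2-7 plus the position-1 ``A``
* ``6mer``    — match to positions 2-7 only

This module derives those site sequences from a microRNA (or its 7-nt seed
region), loads 3'UTR annotation (BED6 + FASTA), and enumerates every exact
site occurrence on every UTR, keeping the longest site at any one locus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction of a DNA sequence, ignoring N positions.

    Parameters
    ----------
    seq : str
        Non-empty DNA string over the alphabet ``ACGTN`` (case-insensitive).

    Returns
    -------
    float
        ``(#G + #C) / (length excluding N)``.

    Raises
    ------
    ValueError
        If ``seq`` is empty, contains characters outside ``ACGTN``, or
        consists entirely of N.
    """
    if not seq:
        raise ValueError("gc_content: empty sequence")
    s = seq.upper()
    if set(s) - set("ACGTN"):
        raise ValueError(f"gc_content: invalid characters {set(s) - set('ACGTN')}")
    n_known = len(s) - s.count("N")
    if n_known == 0:
        raise ValueError("gc_content: sequence is all N")
    return (s.count("G") + s.count("C")) / n_known


def seed_to_site_sequences(mirna_seq: str) -> dict[str, str]:
    """Expand a mature microRNA sequence into its four canonical DNA site types.

    Let ``S`` be the reverse complement (as DNA) of microRNA positions 2-8.
    The site sequences, written 5'->3' on the mRNA, are::

        7mer-m8 : S
        8mer    : S + "A"
        7mer-A1 : S[1:] + "A"
        6mer    : S[1:]

    The appended ``A`` is the adenine opposite microRNA position 1, which is
    recognized directly rather than by pairing.

    Parameters
    ----------
    mirna_seq : str
        Mature microRNA sequence, RNA or DNA alphabet, 5'->3', length >= 8.
    """
    if len(mirna_seq) < 8:
        raise ValueError(
            f"seed_to_site_sequences: microRNA sequence shorter than 8 nt: {mirna_seq!r}"
        )
    dna = mirna_seq.upper().replace("U", "T")
    if set(dna[:8]) - set("ACGT"):
        raise ValueError(f"seed_to_site_sequences: invalid characters in {mirna_seq!r}")
    s = reverse_complement(dna[1:8])  # positions 2-8
    return {
        "7mer-m8": s,
        "8mer": s + "A",
        "7mer-A1": s[1:] + "A",
        "6mer": s[1:],
    }


@dataclass
class UTRRecord:
    """One gene's 3'UTR: genomic intervals plus the spliced sense sequence.

    ``intervals`` are 0-based half-open genomic coordinates, sorted and
    non-overlapping. ``sequence`` is in transcript (5'->3' mRNA sense)
    orientation; for minus-strand genes it is the reverse complement of the
    genomic span, spliced in transcript order.
    """

    gene_id: str
    chrom: str
    strand: str
    intervals: list[tuple[int, int]]
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        ivs = sorted(self.intervals)
        for (a, b), (c, d) in zip(ivs, ivs[1:]):
            if c < b:
                raise ValueError(f"{self.gene_id}: overlapping UTR intervals")
        for a, b in ivs:
            if b <= a:
                raise ValueError(f"{self.gene_id}: empty interval ({a},{b})")
        self.intervals = ivs
        self.sequence = self.sequence.upper()
        width = sum(b - a for a, b in ivs)
        if width != len(self.sequence):
            raise ValueError(
                f"{self.gene_id}: interval width {width} != sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)

    def transcript_to_genomic(self, offset: int, width: int) -> list[tuple[int, int]]:
        """Genomic intervals covered by transcript positions [offset, offset+width).

        Returns a list of (start, end) genomic intervals (possibly split at
        splice junctions), sorted by genomic position.
        """
        if offset < 0 or offset + width > self.length:
            raise ValueError(f"{self.gene_id}: transcript span out of range")
        # transcript order of genomic intervals
        order = self.intervals if self.strand == "+" else self.intervals[::-1]
        out: list[tuple[int, int]] = []
        t = 0
        for a, b in order:
            w = b - a
            lo = max(offset, t)
            hi = min(offset + width, t + w)
            if lo < hi:
                if self.strand == "+":
                    out.append((a + (lo - t), a + (hi - t)))
                else:
                    out.append((b - (hi - t), b - (lo - t)))
            t += w
        return sorted(out)


@dataclass
class SeedMotif:
    """A microRNA family and its candidate site sequences.

    ``seed_region`` is the 7-nt RNA sequence of microRNA positions 2-8;
    ``site_seqs`` maps site type to the DNA sequence matched on the UTR.
    Either may be supplied; sites are derived from the seed when absent.
    """

    family_id: str
    mirna_seq: str | None = None
    seed_region: str | None = None
    site_seqs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.site_seqs:
            if self.mirna_seq:
                self.site_seqs = seed_to_site_sequences(self.mirna_seq)
            elif self.seed_region:
                if len(self.seed_region) != 7:
                    raise ValueError(
                        f"{self.family_id}: seed region must be 7 nt, got {self.seed_region!r}"
                    )
                # prepend a dummy position-1 base; it never enters the sites
                self.site_seqs = seed_to_site_sequences("A" + self.seed_region)
        for t, s in self.site_seqs.items():
            if t not in SITE_TYPES:
                raise ValueError(f"{self.family_id}: unknown site type {t!r}")
            if len(s) not in (6, 7, 8):
                raise ValueError(f"{self.family_id}: site {t} has length {len(s)}")
        if self.seed_region is None and self.mirna_seq is not None:
            self.seed_region = self.mirna_seq.upper().replace("T", "U")[1:8]


@dataclass(frozen=True)
class MRESite:
    """One seed-match occurrence on a UTR (0-based offset on the spliced sequence)."""

    gene_id: str
    family_id: str
    site_type: str
    utr_offset: int
    site_seq: str


class MRECatalog:
    """All candidate MRE sites of a transcriptome, indexed by gene and (gene, family)."""

    def __init__(self, sites: Iterable[MRESite]):
        self.sites: list[MRESite] = sorted(
            sites, key=lambda s: (s.gene_id, s.family_id, s.utr_offset, s.site_type)
        )
        seen = set()
        for s in self.sites:
            key = (s.gene_id, s.family_id, s.site_type, s.utr_offset)
            if key in seen:
                raise ValueError(f"duplicate catalog entry {key}")
            seen.add(key)
        self.by_gene: dict[str, list[MRESite]] = {}
        self.by_pair: dict[tuple[str, str], list[MRESite]] = {}
        for s in self.sites:
            self.by_gene.setdefault(s.gene_id, []).append(s)
            self.by_pair.setdefault((s.gene_id, s.family_id), []).append(s)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.by_pair)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.gene_id, s.family_id, s.site_type, s.utr_offset, s.site_seq) for s in self.sites],
            columns=["gene_id", "family_id", "site_type", "utr_offset", "site_seq"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MRECatalog":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "family_id": str})
        return cls(
            MRESite(r.gene_id, r.family_id, r.site_type, int(r.utr_offset), r.site_seq)
            for r in df.itertuples()
        )


def find_occurrences(seq: str, motif: str) -> list[int]:
    """All start offsets (0-based) of exact, possibly overlapping occurrences."""
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def _suppress_shorter(occs: list[tuple[str, int, str]]) -> list[tuple[str, int, str]]:
    """Keep the longest site per locus: drop occurrences whose interval is
    contained within a retained longer occurrence's interval."""
    kept: list[tuple[int, int, str, str]] = []  # (start, end, type, seq)
    for site_type, off, seq in sorted(occs, key=lambda o: (-len(o[2]), o[1])):
        a, b = off, off + len(seq)
        if any(ka <= a and b <= kb for ka, kb, _, _ in kept):
            continue
        kept.append((a, b, site_type, seq))
    return [(t, a, s) for a, b, t, s in kept]


def build_mre_catalog(
    utrs: Sequence[UTRRecord],
    motifs: Sequence[SeedMotif],
    site_types: Sequence[str] = SITE_TYPES,
) -> MRECatalog:
    """Enumerate every exact site occurrence on every UTR sense sequence.

    Overlapping occurrences are all recorded, except that when a longer site
    type covers a locus the contained shorter-type occurrences of the same
    family are suppressed (one site per (gene, family, locus)). N positions in
    the UTR never match.
    """
    bad = set(site_types) - set(SITE_TYPES)
    if bad:
        raise ValueError(f"unknown site types {bad}")
    sites: list[MRESite] = []
    for motif in motifs:
        wanted = {t: s for t, s in motif.site_seqs.items() if t in site_types}
        if not wanted:
            warnings.warn(f"motif {motif.family_id} has no site sequences; skipped")
            continue
        for utr in utrs:
            occs = [
                (site_type, off, site_seq)
                for site_type, site_seq in wanted.items()
                for off in find_occurrences(utr.sequence, site_seq)
            ]
            sites.extend(
                MRESite(utr.gene_id, motif.family_id, t, off, s)
                for t, off, s in _suppress_shorter(occs)
            )
    return MRECatalog(sites)


def _parse_bed6(bed_path: str | Path) -> list[tuple[str, int, int, str, str]]:
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{bed_path}:{lineno}: BED6 line has {len(f)} fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise ValueError(f"{bed_path}:{lineno}: non-integer coordinates") from e
            if end <= start or start < 0:
                raise ValueError(f"{bed_path}:{lineno}: invalid interval {start}-{end}")
            if f[5] not in "+-":
                raise ValueError(f"{bed_path}:{lineno}: strand must be + or -")
            rows.append((f[0], start, end, f[3], f[5]))
    return rows


def load_utr_annotation(bed_path: str | Path, fasta_path: str | Path) -> list[UTRRecord]:
    """Load 3'UTR records from a BED6 annotation and a FASTA file.

    The FASTA may be either a genome (sequences extracted by coordinates,
    spliced, and reverse-complemented on the minus strand) or per-gene UTR
    sequences whose ids match the BED name column; the mode is detected by
    whether every gene id appears among the FASTA ids.
    """
    rows = _parse_bed6(bed_path)
    if not rows:
        raise ValueError(f"{bed_path}: no BED intervals")
    genes: dict[str, dict] = {}
    for chrom, start, end, name, strand in rows:
        g = genes.setdefault(name, {"chrom": chrom, "strand": strand, "ivs": []})
        if g["chrom"] != chrom or g["strand"] != strand:
            raise ValueError(f"gene {name}: inconsistent chrom/strand across BED lines")
        g["ivs"].append((start, end))
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    fasta_ids = set(fa.keys())
    utr_mode = set(genes) <= fasta_ids
    records = []
    if utr_mode:
        for name in sorted(genes):
            g = genes[name]
            records.append(
                UTRRecord(name, g["chrom"], g["strand"], g["ivs"], str(fa[name][:]))
            )
    else:
        missing = sorted({g["chrom"] for g in genes.values()} - fasta_ids)
        if missing:
            raise ValueError(
                f"contigs in BED absent from FASTA: {', '.join(missing)} "
                "(and gene ids do not match FASTA ids either)"
            )
        for name in sorted(genes):
            g = genes[name]
            ivs = sorted(g["ivs"])
            pieces = [str(fa[g["chrom"]][a:b]) for a, b in ivs]
            seq = "".join(pieces)
            if g["strand"] == "-":
                seq = reverse_complement(seq)
            records.append(UTRRecord(name, g["chrom"], g["strand"], ivs, seq))
    return records


def gene_table(utrs: Sequence[UTRRecord]) -> pd.DataFrame:
    """Per-gene covariate table: 3'UTR length L_g and GC fraction gc_g."""
    return pd.DataFrame(
        [(u.gene_id, u.length, u.gc) for u in utrs],
        columns=["gene_id", "length", "gc"],
    ).set_index("gene_id")


def read_motif_table(path: str | Path) -> list[SeedMotif]:
    """Read a seed-motif TSV (family_id, mirna_seq, seed_region, optional
    site_seq_8mer / site_seq_7m8 / site_seq_7a1 / site_seq_6mer columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "family_id" not in df.columns:
        raise ValueError(f"{path}: missing family_id column")
    colmap = {
        "site_seq_8mer": "8mer",
        "site_seq_7m8": "7mer-m8",
        "site_seq_7a1": "7mer-A1",
        "site_seq_6mer": "6mer",
    }
    motifs = []
    for r in df.itertuples():
        sites = {
            colmap[c]: getattr(r, c).upper()
            for c in colmap
            if c in df.columns and getattr(r, c)
        }
        motifs.append(
            SeedMotif(
                family_id=r.family_id,
                mirna_seq=getattr(r, "mirna_seq", "") or None,
                seed_region=getattr(r, "seed_region", "") or None,
                site_seqs=sites,
            )
        )
    return motifs


def write_motif_table(motifs: Sequence[SeedMotif], path: str | Path) -> None:
    rows = []
    for m in motifs:
        rows.append(
            {
                "family_id": m.family_id,
                "mirna_seq": m.mirna_seq or "",
                "seed_region": m.seed_region or "",
                "site_seq_8mer": m.site_seqs.get("8mer", ""),
                "site_seq_7m8": m.site_seqs.get("7mer-m8", ""),
                "site_seq_7a1": m.site_seqs.get("7mer-A1", ""),
                "site_seq_6mer": m.site_seqs.get("6mer", ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
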