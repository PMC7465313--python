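"""Seeded synthetic diploid genomes for targeted-enrichment experiments.

The generator emulates the layout of a minisatellite fine-mapping locus:
a diploid target chromosome whose two haplotypes differ by the tandem
copy number of a repeat unit (the short/long structural alleles), an
optional high-identity paralog of the locus on another chromosome,
plain background ("decoy") chromosomes, and optional planted SNPs at
guide binding sites.  Output is deterministic for a given config+seed,
byte-for-byte.

Coordinates in the public data model are 1-based inclusive throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from ._dna import random_dna, BASES

HAPLOTYPES = ("hapA", "hapB")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecoySpec:
    """A background chromosome: name, length in bp and GC fraction."""
    name: str
    length: int
    gc: float = 0.4


@dataclass(frozen=True)
class TargetLocusSpec:
    """Minisatellite locus: a tandem repeat array inserted into a chromosome.

    ``insert_pos`` is the 1-based position in the backbone chromosome where
    the array is inserted (the array starts at that coordinate in the final
    haplotype).  ``flank`` bp on either side of the array are counted as
    part of the target window in the truth annotation.
    """
    chrom: str
    insert_pos: int
    flank: int
    repeat_unit: str
    copies_hap_a: int
    copies_hap_b: int


@dataclass(frozen=True)
class ParalogSpec:
    """A duplicated copy of the target locus at ``identity`` (0-1) sequence
    identity, inserted at ``position`` of chromosome ``chrom``."""
    chrom: str
    position: int
    identity: float


@dataclass(frozen=True)
class PlantedSnp:
    """A single substitution on one haplotype, in final haplotype coordinates."""
    haplotype: str  # "hapA" | "hapB"
    position: int
    alt: str


@dataclass(frozen=True)
class PlantedOfftarget:
    """Locus with elevated ligatable-end density (breaks per bp), for
    exercising off-target detection."""
    chrom: str
    position: int
    end_density: float
    span: int = 5000


@dataclass
class SyntheticGenomeConfig:
    seed: int
    decoy_chromosomes: list[DecoySpec]
    target_locus: TargetLocusSpec | None = None
    paralog: ParalogSpec | None = None
    planted_snps: list[PlantedSnp] = field(default_factory=list)
    planted_offtargets: list[PlantedOfftarget] = field(default_factory=list)

    def validate(self) -> None:
        names = [d.name for d in self.decoy_chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        by_name = {d.name: d for d in self.decoy_chromosomes}
        for d in self.decoy_chromosomes:
            if d.length <= 0:
                raise ValueError(f"chromosome {d.name}: length must be positive")
            if not 0.0 <= d.gc <= 1.0:
                raise ValueError(f"chromosome {d.name}: GC fraction outside [0,1]")
        t = self.target_locus
        if t is not None:
            if t.chrom not in by_name:
                raise ValueError(f"target chromosome {t.chrom!r} not declared")
            if t.copies_hap_a < 1 or t.copies_hap_b < 1:
                raise ValueError("repeat copies must be >= 1")
            if not 1 <= t.insert_pos <= by_name[t.chrom].length:
                raise ValueError("target insertion position outside chromosome bounds")
            if not set(t.repeat_unit.upper()) <= set(BASES):
                raise ValueError("repeat unit must be plain ACGT")
        p = self.paralog
        if p is not None:
            if t is None:
                raise ValueError("paralog requires a target locus")
            if p.chrom not in by_name:
                raise ValueError(f"paralog chromosome {p.chrom!r} not declared")
            if not 0.0 <= p.identity <= 1.0:
                raise ValueError("paralog identity must be in [0,1]")
            if not 1 <= p.position <= by_name[p.chrom].length:
                raise ValueError("paralog position outside chromosome bounds")
            if p.chrom == t.chrom:
                # source window of the paralog copy in backbone coordinates
                lo = max(1, t.insert_pos - t.flank)
                hi = t.insert_pos + t.flank
                src_len = hi - lo + 1
                if lo <= p.position <= hi or lo <= p.position + src_len - 1 <= hi \
                        or (p.position <= lo and p.position + src_len - 1 >= hi):
                    raise ValueError(
                        "paralog interval overlaps the target locus on "
                        f"{t.chrom}: paralog at {p.position}, target window "
                        f"[{lo},{hi}]")


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass
class GenomeTruth:
    """Derived ground truth: per-haplotype target windows (contig, start,
    end; 1-based inclusive), repeat copy numbers, paralog interval, SNPs."""
    sequence_names: dict[str, list[str]]
    target_windows: dict[str, tuple[str, int, int]]
    repeat_copies: dict[str, int]
    repeat_unit: str
    paralog_interval: tuple[str, int, int] | None
    snps: list[PlantedSnp]
    offtargets: list[PlantedOfftarget]
    config: SyntheticGenomeConfig

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")

    def to_bed(self, path: str | Path) -> None:
        """Target windows and paralog interval as BED (0-based half-open)."""
        lines = []
        for hap, (contig, start, end) in sorted(self.target_windows.items()):
            lines.append(f"{contig}_{hap}\t{start - 1}\t{end}\ttarget_window_{hap}")
        if self.paralog_interval is not None:
            contig, start, end = self.paralog_interval
            for hap in sorted(self.target_windows):
                lines.append(f"{contig}_{hap}\t{start - 1}\t{end}\tparalog")
        Path(path).write_text("\n".join(lines) + "\n")

    @staticmethod
    def from_json(path: str | Path) -> "GenomeTruth":
        d = json.loads(Path(path).read_text())
        cfg = d["config"]
        config = SyntheticGenomeConfig(
            seed=cfg["seed"],
            decoy_chromosomes=[DecoySpec(**x) for x in cfg["decoy_chromosomes"]],
            target_locus=TargetLocusSpec(**cfg["target_locus"]) if cfg["target_locus"] else None,
            paralog=ParalogSpec(**cfg["paralog"]) if cfg["paralog"] else None,
            planted_snps=[PlantedSnp(**x) for x in cfg["planted_snps"]],
            planted_offtargets=[PlantedOfftarget(**x) for x in cfg["planted_offtargets"]],
        )
        return GenomeTruth(
            sequence_names=d["sequence_names"],
            target_windows={k: tuple(v) for k, v in d["target_windows"].items()},
            repeat_copies=d["repeat_copies"],
            repeat_unit=d["repeat_unit"],
            paralog_interval=tuple(d["paralog_interval"]) if d["paralog_interval"] else None,
            snps=[PlantedSnp(**x) for x in d["snps"]],
            offtargets=[PlantedOfftarget(**x) for x in d["offtargets"]],
            config=config,
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _mutate_to_identity(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability 1-identity."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < 1.0 - identity)[0]
    for i in hits:
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def make_genome(config: SyntheticGenomeConfig):
    """Build the diploid genome described by ``config``.

    Returns ``(haplotypes, truth)`` where ``haplotypes`` maps haplotype tag
    ("hapA"/"hapB") to an ordered ``{chromosome name: sequence}`` dict.
    Decoy chromosomes are shared verbatim between haplotypes; the target
    chromosome differs by repeat copy number and planted SNPs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    backbones = {d.name: random_dna(rng, d.length, d.gc)
                 for d in config.decoy_chromosomes}

    t = config.target_locus
    p = config.paralog

    # paralog source: the hapA target window in backbone coordinates
    paralog_seq = None
    if p is not None:
        lo = max(1, t.insert_pos - t.flank)
        hi = min(len(backbones[t.chrom]), t.insert_pos + t.flank - 1)
        unit = t.repeat_unit.upper()
        source = (backbones[t.chrom][lo - 1:t.insert_pos - 1]
                  + unit * t.copies_hap_a
                  + backbones[t.chrom][t.insert_pos - 1:hi])
        paralog_seq = _mutate_to_identity(source, p.identity, rng)

    haplotypes: dict[str, dict[str, str]] = {}
    target_windows: dict[str, tuple[str, int, int]] = {}
    copies = {"hapA": t.copies_hap_a, "hapB": t.copies_hap_b} if t else {}
    paralog_interval = None

    for hap in HAPLOTYPES:
        chroms: dict[str, str] = {}
        for d in config.decoy_chromosomes:
            seq = backbones[d.name]
            # insertions on this chromosome, applied high-to-low so earlier
            # coordinates are unaffected
            inserts: list[tuple[int, str, str]] = []
            if t is not None and d.name == t.chrom:
                inserts.append((t.insert_pos, t.repeat_unit.upper() * copies[hap], "target"))
            if p is not None and d.name == p.chrom:
                inserts.append((p.position, paralog_seq, "paralog"))
            for pos, ins, label in sorted(inserts, reverse=True):
                seq = seq[:pos - 1] + ins + seq[pos - 1:]
            # final coordinates: shift any interval by lower insertions
            for pos, ins, label in inserts:
                shift = sum(len(i) for q, i, _ in inserts if q < pos)
                start, end = pos + shift, pos + shift + len(ins) - 1
                if label == "target":
                    w_start = max(1, start - t.flank)
                    w_end = min(len(seq), end + t.flank)
                    target_windows[hap] = (d.name, w_start, w_end)
                elif label == "paralog":
                    paralog_interval = (d.name, start, end)
            chroms[d.name] = seq
        haplotypes[hap] = chroms

    for snp in config.planted_snps:
        if snp.haplotype not in haplotypes:
            raise ValueError(f"unknown haplotype {snp.haplotype!r}")
        # SNP positions refer to the target chromosome of that haplotype
        chrom = t.chrom if t is not None else config.decoy_chromosomes[0].name
        seq = haplotypes[snp.haplotype][chrom]
        if not 1 <= snp.position <= len(seq):
            raise ValueError(f"SNP position {snp.position} outside {chrom}")
        haplotypes[snp.haplotype][chrom] = (
            seq[:snp.position - 1] + snp.alt.upper() + seq[snp.position:])

    truth = GenomeTruth(
        sequence_names={hap: [f"{c}_{hap}" for c in haplotypes[hap]] for hap in HAPLOTYPES},
        target_windows=target_windows,
        repeat_copies=copies,
        repeat_unit=t.repeat_unit.upper() if t else "",
        paralog_interval=paralog_interval,
        snps=list(config.planted_snps),
        offtargets=list(config.planted_offtargets),
        config=config,
    )
    return haplotypes, truth


def flatten_haplotypes(haplotypes: Mapping[str, Mapping[str, str]]) -> dict[str, str]:
    """Name-suffixed view ``{chrom}_{hap} -> sequence`` for FASTA export."""
    return {f"{chrom}_{hap}": seq
            for hap, chroms in haplotypes.items()
            for chrom, seq in chroms.items()}


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------
# Hand-written so that parse errors carry line numbers and writes are
# byte-stable (80-column wrap); reading tolerates any wrapping.

def write_fasta(sequences: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 80) -> None:
    items = sequences.items() if isinstance(sequences, Mapping) else list(sequences)
    items = list(items)
    if not items:
        raise ValueError("no sequences to write")
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Order-preserving FASTA reader; malformed input raises with the line
    number of the offence."""
    sequences: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(parts)
                name = line[1:].split()[0] if line[1:].strip() else None
                if name is None:
                    raise ValueError(f"{path}: empty FASTA header at line {lineno}")
                if name in sequences:
                    raise ValueError(f"{path}: duplicate record {name!r} at line {lineno}")
                parts = []
            else:
                if name is None:
                    raise ValueError(
                        f"{path}: sequence data before any header at line {lineno}")
                if not set(line.upper()) <= set("ACGTN"):
                    raise ValueError(
                        f"{path}: non-nucleotide characters at line {lineno}")
                parts.append(line)
    if name is not None:
        sequences[name] = "".join(parts)
    if not sequences:
        raise ValueError(f"{path}: no FASTA records found")
    return sequences
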