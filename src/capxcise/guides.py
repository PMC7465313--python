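"""Guide RNA design: PAM scanning, off-target search and scoring,
orientation relative to a region of interest, SNP cleavage effects, and
panel assembly for the three enrichment strategies (targeted excision,
single-cut walking, tiling).

Conventions
-----------
* A guide occupies a 23-bp genomic site: 20-nt protospacer followed by an
  NGG PAM on the guide's strand.  Coordinates are 1-based inclusive on the
  plus strand of the reference (``end - start + 1 == 23``).
* Protospacer positions are numbered 1..20 with 1 at the PAM-distal end.
  The seed region (PAM-proximal half) is positions 11..20.
* Cas9 cleaves 3 bp upstream of the PAM, leaving blunt ends; the enzyme
  stays bound on the PAM-distal side, so only the PAM-proximal side of a
  cut presents a ligatable end.  ``orientation`` reports whether that free
  end faces a region of interest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._dna import revcomp, encode

SEED_REGION = (11, 20)
GUIDE_LENGTH = 20
SITE_LENGTH = 23

# cleavage-efficiency multipliers by SNP class; the PAM-disrupted class is
# small but nonzero: PAM loss abolishes stable genomic cleavage yet does not
# preclude occasional cutting of naked amplicons.
MULTIPLIER_FULL = 1.0
MULTIPLIER_REDUCED_DISTAL = 0.5
MULTIPLIER_REDUCED_SEED = 0.1
EPSILON_PAM = 0.05


class PanelError(ValueError):
    """No guide panel satisfies the strategy constraints."""


@dataclass(frozen=True)
class Guide:
    name: str
    protospacer: str          # 20 nt, 5'->3' on the guide strand
    pam: str                  # 3 nt NGG on the guide strand
    contig: str
    start: int                # 1-based inclusive, plus strand
    end: int
    strand: str               # "+" | "-"

    def __post_init__(self):
        if len(self.protospacer) != GUIDE_LENGTH:
            raise ValueError(f"{self.name}: protospacer must be 20 nt")
        if len(self.pam) != 3 or not self.pam.upper().endswith("GG"):
            raise ValueError(f"{self.name}: PAM must match NGG, got {self.pam!r}")
        if self.end - self.start + 1 != SITE_LENGTH:
            raise ValueError(f"{self.name}: site must span 23 bp")
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: strand must be '+' or '-'")

    @property
    def site_sequence(self) -> str:
        """protospacer+PAM, 5'->3' on the guide strand."""
        return self.protospacer + self.pam

    def plus_strand_site(self) -> str:
        """The genomic plus-strand slice this guide occupies."""
        return self.site_sequence if self.strand == "+" else revcomp(self.site_sequence)

    def check_against(self, sequence: str) -> None:
        """Verify the invariant that protospacer+PAM reconstructs the
        genomic slice on the stated strand."""
        observed = sequence[self.start - 1:self.end]
        if observed.upper() != self.plus_strand_site().upper():
            raise ValueError(
                f"{self.name}: site sequence does not match the reference at "
                f"{self.contig}:{self.start}-{self.end}({self.strand})")


@dataclass(frozen=True)
class OffTargetHit:
    contig: str
    start: int                # 1-based inclusive plus-strand site interval
    end: int
    strand: str
    mismatches: int
    mismatch_positions: tuple[int, ...]   # protospacer coords, PAM-distal = 1
    has_pam: bool = True

    def __post_init__(self):
        if self.mismatches != len(self.mismatch_positions):
            raise ValueError("mismatch count disagrees with listed positions")


@dataclass(frozen=True)
class CleavageClass:
    kind: str                 # "full" | "reduced" | "none"
    multiplier: float
    mismatch_positions: tuple[int, ...] = ()

    def __post_init__(self):
        if self.kind == "full" and self.multiplier != 1.0:
            raise ValueError("full cleavage implies multiplier 1.0")
        if self.kind == "none" and self.multiplier > EPSILON_PAM:
            raise ValueError("PAM-disrupted class exceeds epsilon")
        if self.kind == "reduced" and not 0.0 < self.multiplier < 1.0:
            raise ValueError("reduced cleavage multiplier must be in (0,1)")


# ---------------------------------------------------------------------------
# PAM scanning
# ---------------------------------------------------------------------------

def scan_pams(sequence: str, contig: str = "seq",
              roi: tuple[int, int] | None = None) -> list[Guide]:
    """Exhaustive NGG scan on both strands.

    Every 20-mer with an adjacent NGG on either strand becomes a candidate.
    Candidates containing ambiguity codes are dropped.  If ``roi`` (1-based
    inclusive) is given, only sites fully inside it are returned.
    """
    n = len(sequence)
    if n < SITE_LENGTH:
        return []
    if roi is not None:
        lo, hi = roi
        if lo < 1 or hi > n or lo > hi:
            raise ValueError(f"ROI [{lo},{hi}] outside sequence of length {n}")
    seq = sequence.upper()
    out: list[Guide] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(len(s) - SITE_LENGTH + 1):
            site = s[i:i + SITE_LENGTH]
            if site[21] != "G" or site[22] != "G":
                continue
            if not set(site) <= {"A", "C", "G", "T"}:
                continue
            if strand == "+":
                start, end = i + 1, i + SITE_LENGTH
            else:
                start, end = n - (i + SITE_LENGTH) + 1, n - i
            if roi is not None and not (roi[0] <= start and end <= roi[1]):
                continue
            out.append(Guide(
                name=f"g_{contig}_{start}_{strand}",
                protospacer=site[:20], pam=site[20:],
                contig=contig, start=start, end=end, strand=strand))
    out.sort(key=lambda g: (g.start, g.strand))
    return out


# ---------------------------------------------------------------------------
# specificity search and score
# ---------------------------------------------------------------------------

def _scan_strand(proto_codes: np.ndarray, seq: str):
    """All 20-mer starts with adjacent GG PAM dinucleotide and the mismatch
    count of each against the protospacer.  Vectorised O(20 n)."""
    codes = encode(seq)
    n = len(codes)
    if n < SITE_LENGTH:
        return np.empty(0, dtype=np.int64), None, None
    m = n - SITE_LENGTH + 1
    mism = np.zeros(m, dtype=np.int16)
    for j in range(GUIDE_LENGTH):
        mism += codes[j:j + m] != proto_codes[j]
    g = np.uint8(2)  # code for G
    pam_ok = (codes[21:21 + m] == g) & (codes[22:22 + m] == g)
    return np.arange(m), mism, pam_ok


def specificity_search(guide: Guide, genome: Mapping[str, str] | str,
                       max_mismatches: int = 4) -> list[OffTargetHit]:
    """All genomic sites matching the protospacer with <= ``max_mismatches``
    and an adjacent NGG, on both strands.  The intended site appears with
    zero mismatches; if no perfect site exists anywhere a warning is issued
    (the guide may target a variant haplotype), not an error.
    """
    if max_mismatches > 6:
        raise ValueError("max_mismatches must be <= 6")
    if isinstance(genome, str):
        genome = {guide.contig: genome}
    proto_codes = encode(guide.protospacer.upper())
    hits: list[OffTargetHit] = []
    for contig, sequence in genome.items():
        seq = sequence.upper()
        n = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            starts, mism, pam_ok = _scan_strand(proto_codes, s)
            if mism is None:
                continue
            keep = np.nonzero((mism <= max_mismatches) & pam_ok)[0]
            codes = encode(s)
            for i in keep:
                window = codes[i:i + GUIDE_LENGTH]
                positions = tuple(int(p) + 1 for p in
                                  np.nonzero(window != proto_codes)[0])
                if strand == "+":
                    start, end = int(i) + 1, int(i) + SITE_LENGTH
                else:
                    start, end = n - (int(i) + SITE_LENGTH) + 1, n - int(i)
                hits.append(OffTargetHit(
                    contig=contig, start=start, end=end, strand=strand,
                    mismatches=len(positions), mismatch_positions=positions))
    hits.sort(key=lambda h: (h.mismatches, h.contig, h.start, h.strand))
    if not any(h.mismatches == 0 for h in hits):
        warnings.warn(
            f"guide {guide.name}: no perfect genomic site found; the target "
            "may carry variants", stacklevel=2)
    return hits


def load_mismatch_penalties(path: str | Path | None = None) -> np.ndarray:
    """20-entry per-position mismatch penalty table (package data by
    default; swappable via ``path``)."""
    if path is None:
        text = resources.files("capxcise.data").joinpath(
            "mismatch_weights.json").read_text()
    else:
        text = Path(path).read_text()
    penalties = np.asarray(json.loads(text)["penalties"], dtype=float)
    if penalties.shape != (20,) or (penalties < 0).any() or (penalties >= 1).any():
        raise ValueError("penalty table must hold 20 values in [0,1)")
    return penalties


def hit_weight(hit: OffTargetHit, penalties: np.ndarray | None = None) -> float:
    """Relative cleavage weight of a site: product of (1 - penalty) over its
    mismatched protospacer positions; a perfect site weighs 1."""
    if penalties is None:
        penalties = load_mismatch_penalties()
    w = 1.0
    for p in hit.mismatch_positions:
        w *= 1.0 - penalties[p - 1]
    return w


def specificity_score(hits: Sequence[OffTargetHit],
                      penalties: np.ndarray | None = None) -> float:
    """Aggregate specificity percentage: 100 * w(intended) / sum(w) over all
    sites.  100 exactly when the intended site is the only hit; any
    secondary hit strictly lowers the score."""
    if not hits:
        raise ValueError("empty hit list: specificity requires the intended site")
    if penalties is None:
        penalties = load_mismatch_penalties()
    perfect = [h for h in hits if h.mismatches == 0]
    if not perfect:
        raise ValueError("hit list lacks the intended (0-mismatch) site")
    total = sum(hit_weight(h, penalties) for h in hits)
    return 100.0 * 1.0 / total


def on_target_activity(guide: Guide, context: str | None = None) -> float:
    """Pluggable on-target activity surrogate in [0, 100].

    Published activity models need extended genomic context and a trained
    regressor; this default is a documented GC/position heuristic only
    (guides with moderate GC and a G at position 20 score higher) and is
    not comparable with any published score.  Swap in a real model by
    passing a callable where the toolkit accepts ``activity_fn``.
    """
    gc = (guide.protospacer.count("G") + guide.protospacer.count("C")) / GUIDE_LENGTH
    score = 100.0 * (1.0 - abs(gc - 0.55) / 0.55)
    if guide.protospacer[19] == "G":
        score = min(100.0, score + 5.0)
    return max(0.0, score)


# ---------------------------------------------------------------------------
# orientation and SNP effects
# ---------------------------------------------------------------------------

def cut_position(guide: Guide) -> int:
    """Blunt-cut coordinate: the cut falls between ``position`` and
    ``position + 1`` (3 bp upstream of the PAM)."""
    return guide.end - 6 if guide.strand == "+" else guide.start + 5


def orientation(guide: Guide, roi: tuple[int, int]) -> str:
    """"toward" iff the ligatable (PAM-proximal) side of the predicted cut
    faces the region of interest; "away" otherwise.  The guide must lie
    outside the ROI."""
    lo, hi = roi
    if not guide.end < lo and not guide.start > hi:
        raise ValueError(
            f"guide {guide.name} overlaps the ROI [{lo},{hi}]; orientation "
            "is defined for flanking guides only")
    p = cut_position(guide)
    free_right = guide.strand == "+"   # free end is PAM-proximal
    if free_right:
        return "toward" if p < lo else "away"
    return "toward" if p >= hi else "away"


def locate_site(guide: Guide, sequence: str, max_mismatches: int = 4):
    """Best match of the guide's 23-bp site in ``sequence`` on the guide's
    strand, allowing protospacer mismatches (PAM unconstrained).

    Returns ``(start, end, mismatch_positions, pam)`` with 1-based
    coordinates; raises if no site within ``max_mismatches``.
    """
    seq = sequence.upper()
    n = len(seq)
    proto_codes = encode(guide.protospacer.upper())
    best = None
    s = seq if guide.strand == "+" else revcomp(seq)
    starts, mism, _ = _scan_strand(proto_codes, s)
    if mism is not None:
        order = np.argsort(mism, kind="stable")
        i = int(order[0])
        if mism[i] <= max_mismatches:
            codes = encode(s)
            window = codes[i:i + GUIDE_LENGTH]
            positions = tuple(int(p) + 1 for p in np.nonzero(window != proto_codes)[0])
            pam = s[i + 20:i + 23]
            if guide.strand == "+":
                best = (i + 1, i + SITE_LENGTH, positions, pam)
            else:
                best = (n - (i + SITE_LENGTH) + 1, n - i, positions, pam)
    if best is None:
        raise ValueError(
            f"guide {guide.name}: no site within {max_mismatches} mismatches")
    return best


def snp_effect(guide: Guide, haplotype_sequence: str,
               max_mismatches: int = 4) -> CleavageClass:
    """Predicted cleavage class of the guide on a haplotype.

    PAM no longer NGG -> "none" (epsilon multiplier); mismatch within the
    seed region (positions 11-20) -> "reduced" at the seed multiplier;
    distal-only mismatches -> "reduced" at the distal multiplier; perfect
    site -> "full".
    """
    start, end, positions, pam = locate_site(guide, haplotype_sequence, max_mismatches)
    if not pam.upper().endswith("GG"):
        return CleavageClass("none", EPSILON_PAM, positions)
    if not positions:
        return CleavageClass("full", MULTIPLIER_FULL)
    if any(SEED_REGION[0] <= p <= SEED_REGION[1] for p in positions):
        return CleavageClass("reduced", MULTIPLIER_REDUCED_SEED, positions)
    return CleavageClass("reduced", MULTIPLIER_REDUCED_DISTAL, positions)


# ---------------------------------------------------------------------------
# panel planning
# ---------------------------------------------------------------------------

def replace_coords(guide: Guide, offset: int) -> Guide:
    """Shift a guide found on a subsequence back onto full-sequence
    coordinates."""
    from dataclasses import replace
    start, end = guide.start + offset, guide.end + offset
    return replace(guide, start=start, end=end,
                   name=f"g_{guide.contig}_{start}_{guide.strand}")

def plan_panel(sequence: str, roi: tuple[int, int], strategy: str,
               contig: str = "seq", *, guides_per_side: int = 1,
               search_margin: int = 3000, known_end: str = "left",
               tile_spacing: tuple[int, int] = (5000, 10000),
               min_separation: int = 50) -> list[Guide]:
    """Assemble a guide panel for a region of interest.

    Strategies:
      * ``excision`` - >=1 guide on each side of the ROI, all oriented
        toward it, cut sites flanking the ROI (for loci whose both ends
        are known).
      * ``single_cut`` - exactly one guide at the stated known end
        (``known_end``), oriented toward the unknown side.
      * ``tiling`` - successive cut sites spaced 5-10 kb apart covering
        the ROI (for long loci).
    """
    lo, hi = roi
    if lo < 1 or hi > len(sequence) or lo > hi:
        raise PanelError(f"ROI [{lo},{hi}] outside sequence")
    # scan only the stretch any strategy can draw from
    reach = max(search_margin, tile_spacing[1]) + SITE_LENGTH
    region_lo = max(1, lo - reach)
    region_hi = min(len(sequence), hi + reach)
    offset = region_lo - 1
    candidates = [replace_coords(g, offset)
                  for g in scan_pams(sequence[region_lo - 1:region_hi], contig)]

    def toward_candidates(side: str) -> list[Guide]:
        picked = []
        for g in candidates:
            if side == "left" and not g.end < lo:
                continue
            if side == "right" and not g.start > hi:
                continue
            if abs(cut_position(g) - (lo if side == "left" else hi)) > search_margin:
                continue
            if orientation(g, roi) == "toward":
                picked.append(g)
        # nearest cut to the ROI first
        anchor = lo if side == "left" else hi
        picked.sort(key=lambda g: abs(cut_position(g) - anchor))
        return picked

    if strategy == "excision":
        panel: list[Guide] = []
        for side in ("left", "right"):
            chosen: list[Guide] = []
            for g in toward_candidates(side):
                if all(abs(cut_position(g) - cut_position(c)) >= min_separation
                       for c in chosen):
                    chosen.append(g)
                if len(chosen) == guides_per_side:
                    break
            if len(chosen) < guides_per_side:
                raise PanelError(
                    f"excision: only {len(chosen)} toward-oriented candidates "
                    f"within {search_margin} bp on the {side} side of the ROI "
                    f"(needed {guides_per_side})")
            panel.extend(chosen)
        panel.sort(key=lambda g: g.start)
        return panel

    if strategy == "single_cut":
        if known_end not in ("left", "right"):
            raise PanelError("known_end must be 'left' or 'right'")
        cands = toward_candidates(known_end)
        if not cands:
            raise PanelError(
                f"single_cut: no toward-oriented candidate within "
                f"{search_margin} bp of the {known_end} end")
        return [cands[0]]

    if strategy == "tiling":
        min_gap, max_gap = tile_spacing
        by_cut = sorted(candidates, key=cut_position)
        if not by_cut:
            raise PanelError("tiling: no NGG candidates in the sequence")
        # first cut at or just before the ROI start
        before = [g for g in by_cut if cut_position(g) <= lo]
        current = before[-1] if before else by_cut[0]
        if cut_position(current) > lo + max_gap:
            raise PanelError("tiling: no candidate near the ROI start")
        panel = [current]
        while cut_position(current) < hi:
            window = [g for g in by_cut
                      if min_gap <= cut_position(g) - cut_position(current) <= max_gap]
            if not window:
                raise PanelError(
                    f"tiling: no candidate {min_gap}-{max_gap} bp downstream of "
                    f"cut {cut_position(current)}")
            current = window[-1]    # maximal progress within the band
            panel.append(current)
        return panel

    raise PanelError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# TSV / BED interfaces
# ---------------------------------------------------------------------------

GUIDE_COLUMNS = ["Name", "Sequence", "Chr", "Start", "End", "Strand"]


def guides_to_tsv(guides: Iterable[Guide], path: str | Path) -> None:
    rows = [{"Name": g.name, "Sequence": g.site_sequence, "Chr": g.contig,
             "Start": g.start, "End": g.end, "Strand": g.strand}
            for g in guides]
    pd.DataFrame(rows, columns=GUIDE_COLUMNS).to_csv(path, sep="\t", index=False)


def guides_from_tsv(path: str | Path) -> list[Guide]:
    df = pd.read_csv(path, sep="\t")
    missing = set(GUIDE_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing guide columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        seq = str(row["Sequence"]).upper()
        strand = str(row.get("Strand", "+"))
        out.append(Guide(name=str(row["Name"]), protospacer=seq[:20],
                         pam=seq[20:], contig=str(row["Chr"]),
                         start=int(row["Start"]), end=int(row["End"]),
                         strand=strand))
    return out


def reference_guides() -> list[Guide]:
    """The packaged four-guide panel flanking the apple MYB10 red-flesh
    minisatellite locus (two upstream, two downstream of the gene)."""
    with resources.as_file(resources.files("capxcise.data")
                           .joinpath("myb10_guides.tsv")) as p:
        return guides_from_tsv(p)


def hits_to_tsv(hits: Iterable[OffTargetHit], path: str | Path) -> None:
    rows = [{"contig": h.contig, "sstart": h.start, "send": h.end,
             "strand": h.strand, "mism": h.mismatches,
             "pident": round(100.0 * (20 - h.mismatches) / 20, 2),
             "positions": ",".join(map(str, h.mismatch_positions)) or "."}
            for h in hits]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def hits_to_bed(hits: Iterable[OffTargetHit], path: str | Path) -> None:
    lines = [f"{h.contig}\t{h.start - 1}\t{h.end}\tmm{h.mismatches}\t"
             f"{20 - h.mismatches}\t{h.strand}" for h in hits]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
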