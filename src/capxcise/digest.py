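"""In-silico Cas9 digestion with end-state bookkeeping.

Cas9 cleaves both strands 3 bp upstream of the PAM, producing a blunt end.
For a site occupying 1-based positions ``[start, end]`` the cut therefore
falls between ``end-6`` and ``end-5`` on a forward guide and between
``start+5`` and ``start+6`` on a reverse guide.  After cleavage the enzyme
remains bound on the PAM-distal side, blocking adapter ligation there; the
PAM-proximal side presents a free 5'-phosphorylated blunt end.

The enrichment pipeline order is: dephosphorylate pre-existing ends, cut,
dA-tail everything, ligate adapters.  Fragment end states track
(phosphorylated, blocked, dA-tailed, adapter) through those stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .guides import Guide, CleavageClass, snp_effect, cut_position, locate_site


@dataclass(frozen=True)
class CutSite:
    """A blunt cut between ``position`` and ``position + 1`` (1-based)."""
    contig: str
    position: int
    guide_name: str
    blocked_side: str       # "left" | "right": the PAM-distal side

    def __post_init__(self):
        if self.blocked_side not in ("left", "right"):
            raise ValueError("blocked_side must be 'left' or 'right'")

    @property
    def free_side(self) -> str:
        return "right" if self.blocked_side == "left" else "left"


def cut_site(guide: Guide) -> CutSite:
    """Predicted cut for a guide; the blocked side is PAM-distal (left of
    the cut for forward guides, right for reverse guides)."""
    return CutSite(contig=guide.contig, position=cut_position(guide),
                   guide_name=guide.name,
                   blocked_side="left" if guide.strand == "+" else "right")


@dataclass
class EndState:
    phosphorylated: bool = True
    blocked: bool = False
    da_tailed: bool = False
    adapter: bool = False
    origin: str = "natural"     # "natural" | "cut"
    leaked: bool = False        # blocked cut end that later shed Cas9

    def validate(self) -> None:
        if self.adapter and not (self.phosphorylated and self.da_tailed
                                 and not self.blocked):
            raise ValueError(
                "adapter requires a phosphorylated, dA-tailed, unblocked end")


@dataclass
class Fragment:
    """A linear piece of a template; interval is 1-based inclusive in
    template coordinates."""
    template_id: str
    start: int
    end: int
    left_end: EndState = field(default_factory=EndState)
    right_end: EndState = field(default_factory=EndState)
    haplotype: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def ends(self):
        yield "left", self.left_end
        yield "right", self.right_end


def template_fragment(template_id: str, length: int, haplotype: str = "") -> Fragment:
    """An undigested template as a single fragment with natural,
    phosphorylated, unblocked ends."""
    return Fragment(template_id=template_id, start=1, end=length,
                    haplotype=haplotype)


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def _effective(cls: CleavageClass, rng: np.random.Generator | None) -> bool:
    """Whether a cut happens.  Multiplier 1 / 0 is deterministic; anything
    in between is a seeded draw."""
    if cls.multiplier >= 1.0:
        return True
    if cls.multiplier <= 0.0:
        return False
    if rng is None:
        raise ValueError(
            "stochastic cleavage class requires a random generator")
    return bool(rng.random() < cls.multiplier)


def digest_fragment(fragment: Fragment,
                    cuts: Sequence[tuple[CutSite, CleavageClass]],
                    rng: np.random.Generator | None = None) -> list[Fragment]:
    """Apply cut sites to one fragment, preserving its outer end states.

    Cut positions must lie strictly inside the fragment interval; two cuts
    at the same position are an error.  New ends are phosphorylated; the
    PAM-distal side of each cut is blocked.
    """
    applied: list[CutSite] = []
    for site, cls in cuts:
        if not fragment.start <= site.position < fragment.end:
            continue
        if _effective(cls, rng):
            applied.append(site)
    positions = [c.position for c in applied]
    if len(positions) != len(set(positions)):
        dup = sorted(p for p in positions if positions.count(p) > 1)
        raise ValueError(f"two cuts at the same position: {sorted(set(dup))}")
    applied.sort(key=lambda c: c.position)

    if not applied:
        return [fragment]

    pieces: list[Fragment] = []
    left_bound = fragment.start
    left_state = fragment.left_end
    for site in applied:
        right_state = EndState(phosphorylated=True,
                               blocked=site.blocked_side == "left",
                               origin="cut")
        pieces.append(Fragment(fragment.template_id, left_bound, site.position,
                               left_end=left_state, right_end=right_state,
                               haplotype=fragment.haplotype))
        left_state = EndState(phosphorylated=True,
                              blocked=site.blocked_side == "right",
                              origin="cut")
        left_bound = site.position + 1
    pieces.append(Fragment(fragment.template_id, left_bound, fragment.end,
                           left_end=left_state, right_end=fragment.right_end,
                           haplotype=fragment.haplotype))
    return pieces


def digest_template(template_id: str, length: int, guides: Sequence[Guide],
                    haplotype_sequence: str | None = None,
                    haplotype: str = "",
                    rng: np.random.Generator | None = None) -> list[Fragment]:
    """Digest a whole template with a guide set.

    When ``haplotype_sequence`` is given, each guide's cleavage class is
    predicted from the sequence (SNP effects included) and its cut site is
    placed at the located site; otherwise cleavage is assumed full at the
    guide's stated coordinates.
    """
    cuts: list[tuple[CutSite, CleavageClass]] = []
    for g in guides:
        if haplotype_sequence is not None:
            start, end, positions, pam = locate_site(g, haplotype_sequence)
            cls = snp_effect(g, haplotype_sequence)
            located = replace(g, start=start, end=end) if (start, end) != (g.start, g.end) else g
            site = cut_site(located)
        else:
            cls = CleavageClass("full", 1.0)
            site = cut_site(g)
        cuts.append((site, cls))
    frag = template_fragment(template_id, length, haplotype)
    return digest_fragment(frag, cuts, rng)


# ---------------------------------------------------------------------------
# end chemistry
# ---------------------------------------------------------------------------

def dephosphorylate(fragments: Iterable[Fragment], efficiency: float,
                    rng: np.random.Generator | None = None) -> list[Fragment]:
    """Remove 5' phosphates from pre-existing ends with the stated
    probability.  Applied before digestion so that cut ends introduced
    later keep their phosphates."""
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError(f"efficiency must be in [0,1], got {efficiency}")
    if 0.0 < efficiency < 1.0 and rng is None:
        raise ValueError("fractional efficiency requires a random generator")
    out = []
    for f in fragments:
        for _, state in f.ends():
            if state.phosphorylated and state.origin == "natural":
                if efficiency >= 1.0 or (efficiency > 0.0 and rng.random() < efficiency):
                    state.phosphorylated = False
        out.append(f)
    return out


def da_tail(fragments: Iterable[Fragment]) -> list[Fragment]:
    """dA-tail every end (the tailing reaction acts on all accessible
    blunt ends)."""
    out = []
    for f in fragments:
        for _, state in f.ends():
            state.da_tailed = True
        out.append(f)
    return out


# ---------------------------------------------------------------------------
# amplicon prediction and on-target window
# ---------------------------------------------------------------------------

def predict_amplicon_fragments(forward_start: int, reverse_end: int,
                               guide: Guide) -> list[int]:
    """Expected fragment lengths (bp) after cutting a PCR amplicon spanning
    ``[forward_start, reverse_end]`` with one guide; a cut outside the
    amplicon leaves it intact."""
    if reverse_end < forward_start:
        raise ValueError("amplicon end precedes its start")
    length = reverse_end - forward_start + 1
    p = cut_position(guide)
    if forward_start <= p < reverse_end:
        return [p - forward_start + 1, reverse_end - p]
    return [length]


def on_target_window(guides: Sequence[Guide], mode: str = "cut_span"):
    """The target window implied by a flanking guide panel.

    ``cut_span``: inclusive interval between the outermost predicted blunt
    cuts (leftmost cut position + 1 through rightmost cut position) - the
    span of DNA actually excised between the outermost cuts.

    ``site_span``: the start-to-start distance of the innermost flanking
    guide pair (the pair across the widest gap between consecutive guide
    starts), i.e. the locus length quoted between the inner guides.

    Returns ``(contig, start, end, length)``.
    """
    if len(guides) < 2:
        raise ValueError(
            "on_target_window needs >= 2 guides; with a single guide use the "
            "single_cut strategy")
    contigs = {g.contig for g in guides}
    if len(contigs) != 1:
        raise ValueError(f"guides span multiple contigs: {sorted(contigs)}")
    contig = contigs.pop()
    if mode == "cut_span":
        cuts = [cut_position(g) for g in guides]
        lo, hi = min(cuts), max(cuts)
        return (contig, lo + 1, hi, hi - lo)
    if mode == "site_span":
        starts = sorted(g.start for g in guides)
        gaps = [(starts[i + 1] - starts[i], i) for i in range(len(starts) - 1)]
        width, i = max(gaps)
        return (contig, starts[i], starts[i + 1], width)
    raise ValueError(f"unknown mode {mode!r}")
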