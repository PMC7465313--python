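"""Nanopore enrichment-library read simulator.

Models the library mechanistically: sequencing adapters ligate to
phosphorylated, dA-tailed, unblocked ends, so reads start at free Cas9 cut
ends (abundant: many cleaved molecules share the same two cut positions)
and at residual genomic break ends that escaped dephosphorylation
(background, scattered).  Blocked (Cas9-bound, PAM-distal) ends receive
adapters only at a small leak rate.  Each read extends from its adapter
into the molecule on the strand implied by the end, up to the fragment
boundary, a pore-truncation draw, and the configured maximum.

Per-base qualities come from a named profile (two bundled profiles mirror
the two common base callers' median read qualities, ~9.1 and ~11.2);
substitution/insertion/deletion errors are injected at configured rates.
Every read carries a truth record (haplotype, interval, strand, source
class) and the run emits truth alignments in PAF convention against the
haplotype sequences.

The default configuration is the "calibrated_run" regime: its background
break density and cut-end molecule abundance are calibrated - not measured
- so that a 7,000-read run on the bundled synthetic diploid genome sits in
the enrichment regime of a real targeted-excision MinION run (~3% of reads
on-target).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._dna import revcomp, encode, decode
from .digest import Fragment
from .qc import AlignmentRecord


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QualityProfile:
    name: str
    median_q: float
    spread: float = 1.0


# bundled profiles named after the two base callers' Phred medians
QUALITY_PROFILES = {
    "caller_a": QualityProfile("caller_a", 9.11, 1.0),
    "caller_b": QualityProfile("caller_b", 11.22, 1.0),
}


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error rates.  The defaults total ~7.6%, matching the error
    probability implied by the default quality profile's median Phred
    (10^(-11.22/10) ~ 0.076)."""
    substitution: float = 0.04
    insertion: float = 0.018
    deletion: float = 0.018

    def validate(self):
        for r in (self.substitution, self.insertion, self.deletion):
            if not 0.0 <= r < 1.0:
                raise ValueError("error rates must be in [0,1)")


@dataclass(frozen=True)
class ReadLengthModel:
    truncation_per_kb: float = 0.005  # per-kb probability the pore read ends
    max_length: int = 100_000


@dataclass
class SimConfig:
    """Simulation parameters.  The defaults are the shipped
    "calibrated_run" regime (see module docstring): ``background_break_rate``
    is the aggregate density of random breaks per bp across the sequenced
    molecule population, and ``cut_end_molecules`` the number of
    target-chromosome molecules carried through digestion (each with
    independent cleavage draws), whose cut ends enter the adapter pool."""
    n_reads: int = 7000
    dephosphorylation_efficiency: float = 0.95
    background_break_rate: float = 0.025
    blocked_end_leak: float = 0.05
    cut_end_molecules: int = 100
    background_length_median: float = 10_000.0
    background_length_sigma: float = 1.064
    read_length_model: ReadLengthModel = field(default_factory=ReadLengthModel)
    quality_profile: str = "caller_b"
    error_model: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        for name in ("dephosphorylation_efficiency", "blocked_end_leak"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.background_break_rate < 0:
            raise ValueError("background_break_rate must be >= 0")
        if self.quality_profile not in QUALITY_PROFILES:
            raise ValueError(f"unknown quality profile {self.quality_profile!r}")
        self.error_model.validate()


def calibrated_run(seed: int = 0, **overrides) -> SimConfig:
    """The shipped calibrated enrichment regime."""
    cfg = SimConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadTruth:
    haplotype: str
    contig: str
    start: int        # 1-based inclusive on the haplotype sequence
    end: int
    strand: str
    source: str       # "cut" | "background" | "leak"


@dataclass
class SimulatedRead:
    id: str
    sequence: str
    qualities: np.ndarray     # Phred scores, one per base
    truth: ReadTruth


def mean_read_quality(qualities: Sequence[float] | np.ndarray) -> float:
    """Phred of the arithmetic mean error probability (probability-space
    mean); this is the standard per-read mean quality used for pass
    filtering."""
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        raise ValueError("empty quality vector")
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


# ---------------------------------------------------------------------------
# adapter ligation
# ---------------------------------------------------------------------------

def ligate_adapters(fragments: Iterable[Fragment], config: SimConfig,
                    rng: np.random.Generator | None = None) -> list[Fragment]:
    """Set adapter flags.  Eligible = phosphorylated, dA-tailed, unblocked.
    Blocked ends leak adapters at ``blocked_end_leak``."""
    if config.blocked_end_leak > 0 and rng is None:
        raise ValueError("nonzero blocked_end_leak requires a random generator")
    out = []
    for f in fragments:
        for _, state in f.ends():
            if not (state.phosphorylated and state.da_tailed):
                continue
            if not state.blocked:
                state.adapter = True
            elif config.blocked_end_leak > 0 and rng.random() < config.blocked_end_leak:
                # Cas9 released its grip on this molecule's PAM-distal end
                state.adapter = True
                state.blocked = False
                state.leaked = True
            state.validate()
        out.append(f)
    return out


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------

def apply_errors(sequence: str, model: ErrorModel,
                 rng: np.random.Generator) -> str:
    """Inject substitutions, insertions and deletions at the configured
    per-base rates."""
    codes = encode(sequence)
    n = codes.size
    if n == 0:
        return ""
    if model.deletion > 0:
        codes = codes[rng.random(n) >= model.deletion]
    m = codes.size
    if m and model.substitution > 0:
        sub = rng.random(m) < model.substitution
        k = int(sub.sum())
        if k:
            codes = codes.copy()
            codes[sub] = (codes[sub] + rng.integers(1, 4, k).astype(np.uint8)) % 4
    if m and model.insertion > 0:
        k = int(rng.binomial(m, model.insertion))
        if k:
            pos = np.sort(rng.integers(0, m + 1, k))
            codes = np.insert(codes, pos, rng.integers(0, 4, k).astype(np.uint8))
    return decode(codes)


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Source:
    haplotype: str
    contig: str
    position: int     # read start, 1-based
    direction: int    # +1 rightward, -1 leftward
    limit: int | None  # molecule extent from the start (None: draw lognormal)
    kind: str         # "cut" | "background" | "leak"
    weight: float


@dataclass
class SimRun:
    reads: list[SimulatedRead]
    config: SimConfig

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                qual = (np.asarray(r.qualities, dtype=np.uint8) + 33).tobytes()
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual.decode('ascii')}\n")

    def truth_alignments(self,
                         contig_lengths: Mapping[str, int]) -> list[AlignmentRecord]:
        """Truth records in PAF convention against the haplotype sequences
        (target names are ``{contig}_{haplotype}``)."""
        out = []
        for r in self.reads:
            t = r.truth
            tname = f"{t.contig}_{t.haplotype}"
            span = t.end - t.start + 1
            out.append(AlignmentRecord(
                qname=r.id, qlen=len(r.sequence), qstart=0, qend=len(r.sequence),
                strand=t.strand, tname=tname, tlen=contig_lengths[tname],
                tstart=t.start - 1, tend=t.end, nmatch=span, blocklen=span,
                mapq=60))
        return out

    def truth_bed(self, path: str | Path) -> None:
        lines = [f"{r.truth.contig}_{r.truth.haplotype}\t{r.truth.start - 1}\t"
                 f"{r.truth.end}\t{r.id}\t0\t{r.truth.strand}\t{r.truth.source}"
                 for r in self.reads]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _collect_sources(haplotypes, fragments, config, rng,
                     planted_offtargets=()) -> list[_Source]:
    sources: list[_Source] = []
    for f in fragments:
        for side, state in f.ends():
            if not state.adapter:
                continue
            if state.leaked:
                kind = "leak"
            elif state.origin == "cut":
                kind = "cut"
            else:
                kind = "background"
            if side == "left":
                sources.append(_Source(f.haplotype, f.template_id, f.start, +1,
                                       f.length, kind, 1.0))
            else:
                sources.append(_Source(f.haplotype, f.template_id, f.end, -1,
                                       f.length, kind, 1.0))
    survive = 1.0 - config.dephosphorylation_efficiency
    for hap, chroms in haplotypes.items():
        for contig, seq in chroms.items():
            L = len(seq)
            n_breaks = rng.poisson(config.background_break_rate * L)
            if n_breaks:
                positions = rng.integers(1, L, size=n_breaks)
                keep_r = rng.random(n_breaks) < survive
                keep_l = rng.random(n_breaks) < survive
                for p in positions[keep_r]:
                    sources.append(_Source(hap, contig, int(p) + 1, +1, None,
                                           "background", 1.0))
                for p in positions[keep_l]:
                    sources.append(_Source(hap, contig, int(p), -1, None,
                                           "background", 1.0))
            for ot in planted_offtargets:
                if ot.chrom != contig:
                    continue
                n_extra = rng.poisson(ot.end_density * ot.span)
                lo = max(1, ot.position - ot.span // 2)
                hi = min(L, ot.position + ot.span // 2)
                if n_extra and hi > lo:
                    for p in rng.integers(lo, hi, size=n_extra):
                        d = +1 if rng.random() < 0.5 else -1
                        sources.append(_Source(hap, contig, int(p), d, None,
                                               "background", 1.0))
    return sources


def simulate_run(haplotypes: Mapping[str, Mapping[str, str]],
                 fragments: Sequence[Fragment], config: SimConfig,
                 rng: np.random.Generator | None = None,
                 planted_offtargets: Sequence = ()) -> SimRun:
    """Sample a full sequencing run.

    ``fragments`` must already carry adapter flags (see
    :func:`ligate_adapters`); each read starts at an adapter-bearing end -
    either a replicated cut end or a residual background end - and extends
    into its molecule on the implied strand.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    sources = _collect_sources(haplotypes, fragments, config, rng,
                               planted_offtargets)
    if not sources:
        raise ValueError("no possible read sources: no adapters and no "
                         "background breaks")
    weights = np.array([s.weight for s in sources])
    probs = weights / weights.sum()
    choice = rng.choice(len(sources), size=config.n_reads, p=probs)

    profile = QUALITY_PROFILES[config.quality_profile]
    rlm = config.read_length_model
    mean_trunc = (1000.0 / rlm.truncation_per_kb
                  if rlm.truncation_per_kb > 0 else math.inf)
    mu = math.log(config.background_length_median)
    sigma = config.background_length_sigma

    reads: list[SimulatedRead] = []
    for idx, si in enumerate(choice):
        s = sources[si]
        chrom_len = len(haplotypes[s.haplotype][s.contig])
        if s.limit is not None:
            molecule = s.limit
        else:
            molecule = rng.lognormal(mu, sigma)
        trunc = rng.exponential(mean_trunc) if math.isfinite(mean_trunc) else math.inf
        boundary = chrom_len - s.position + 1 if s.direction > 0 else s.position
        length = int(max(1, min(molecule, trunc, rlm.max_length, boundary)))
        if s.direction > 0:
            start, end = s.position, s.position + length - 1
            strand = "+"
        else:
            start, end = s.position - length + 1, s.position
            strand = "-"
        template = haplotypes[s.haplotype][s.contig][start - 1:end]
        if strand == "-":
            template = revcomp(template)
        seq = apply_errors(template, config.error_model, rng)
        mean_q = max(2.0, rng.normal(profile.median_q, profile.spread))
        quals = np.clip(np.rint(rng.normal(mean_q, 2.0, size=len(seq))),
                        2, 41).astype(np.uint8)
        reads.append(SimulatedRead(
            id=f"read_{idx:06d}", sequence=seq, qualities=quals,
            truth=ReadTruth(s.haplotype, s.contig, start, end, strand, s.kind)))
    return SimRun(reads=reads, config=config)
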