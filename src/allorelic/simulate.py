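"""Deterministic allotetraploid fixture generator with machine-readable truth.

The generator builds two diverged diploid progenitors (A and B), a wild donor
related to A, and an AABB tetraploid whose scaffolds are mutated copies of the
progenitor chromosomes with planted structure: inversions
(reverse-complemented spans), tetrasomic tracts (both homeologs carry the
same progenitor's sequence), homeologous exchange tracts (sequence swapped
between homeologs), one donor introgression, and N-gap contig joins.  A
donor-derived alternate haplotype scaffold, a best-placement read-mapping
PAF, a trio VCF with a controllable outcross fraction, and a gene BED
complete the fixture.

All mutations are substitutions, so coordinate maps between genomes are
length-preserving and alignment records can be emitted exactly from the
provenance bookkeeping rather than from an aligner: each record's identity
equals one minus the realized mismatch fraction of its block.  Comparisons
across the species boundary (donor-derived vs progenitor-derived sequence)
are emitted only over a regular grid of conserved islands, mimicking the
fragmented, low-coverage but high-identity alignments a diverged wild
relative produces; the donor is mutated at a reduced rate inside those
islands.  Same seed implies byte-identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

# base coding: 0..3 = ACGT, 4 = N
_ALPHABET = np.frombuffer(b"ACGTN", dtype=np.uint8)
ORIGIN_A, ORIGIN_B, ORIGIN_D, ORIGIN_GAP = 0, 1, 2, 3
_ORIGIN_NAMES = {ORIGIN_A: "A", ORIGIN_B: "B", ORIGIN_D: "D", ORIGIN_GAP: "gap"}


@dataclass
class SimConfig:
    """Study conditions for the synthetic allotetraploid fixture.

    Divergences are substitution fractions; the progenitors differ by
    ``ancestor_divergence``, each tetraploid subgenome differs from its
    progenitor by ``genotype_divergence``, and the wild donor differs from
    progenitor A by ``donor_divergence`` (reduced by ``island_factor``
    inside conserved islands).  Planted features use scaffold coordinates on
    the tetraploid; pair-level tracts name the chromosome pair.
    """

    seed: int = 42
    n_chrom_pairs: int = 2
    chrom_len: int = 2_000_000
    ancestor_divergence: float = 0.10
    genotype_divergence: float = 0.02
    donor_divergence: float = 0.08
    island_factor: float = 0.3
    island_period: int = 100_000
    island_offset: int = 40_000
    island_len: int = 15_000
    # (scaffold, start, end)
    inversions: list = field(
        default_factory=lambda: [
            ("chr01_A", 800_000, 900_000),
            ("chr02_B", 300_000, 450_000),
        ]
    )
    # (pair, start, end): sequence swapped between homeologs
    exchange_tracts: list = field(default_factory=lambda: [("chr02", 1_200_000, 1_600_000)])
    # (pair, start, end, ancestor): both homeologs carry `ancestor` sequence
    tetrasomic_tracts: list = field(default_factory=lambda: [("chr01", 200_000, 600_000, "A")])
    # (scaffold, start, end): donor-derived tract
    introgression_tract: Optional[tuple] = ("chr01_A", 1_400_000, 1_800_000)
    # N-gap spans applied to every main tetraploid scaffold; the first gap
    # edge sits 1 kb from the chr02_B inversion boundary, planting one
    # breakpoint-proximal inversion (the mis-orientation signature the
    # inversion filter exists to catch)
    gap_spans: list = field(default_factory=lambda: [(451_000, 461_000), (1_950_000, 1_960_000)])
    alt_haplotype: bool = True  # emit the donor-derived chr01_A_alt scaffold
    read_len: int = 10_000
    outcross_fraction: float = 0.1
    n_trio_sites: int = 4000
    window: int = 100_000

    def validate(self) -> None:
        for frac in (self.ancestor_divergence, self.genotype_divergence,
                     self.donor_divergence, self.outcross_fraction):
            if not 0 <= frac < 0.5:
                raise ValueError(f"fraction {frac} outside [0, 0.5)")
        spans: dict[str, list[tuple[int, int]]] = {}
        for scaf, s, e in self.inversions:
            spans.setdefault(scaf, []).append((s, e))
        for pair, s, e in self.exchange_tracts:
            for sub in "AB":
                spans.setdefault(f"{pair}_{sub}", []).append((s, e))
        for pair, s, e, anc in self.tetrasomic_tracts:
            other = "B" if anc == "A" else "A"
            spans.setdefault(f"{pair}_{other}", []).append((s, e))
        if self.introgression_tract:
            scaf, s, e = self.introgression_tract
            spans.setdefault(scaf, []).append((s, e))
        for scaf, ivs in spans.items():
            ivs = sorted(ivs)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"planted features overlap on {scaf}: {(s1, e1)} and {(s2, e2)}"
                    )
            for s, e in ivs:
                if not (0 <= s < e <= self.chrom_len):
                    raise ValueError(f"feature {(s, e)} outside chromosome on {scaf}")


@dataclass
class Fixture:
    """Paths and truth for one generated fixture."""

    outdir: str
    config: SimConfig
    paths: dict
    truth: dict


# ---------------------------------------------------------------------------
# sequence primitives


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate) -> np.ndarray:
    """Substitute bases at ``rate`` (scalar or per-position array); a mutated
    base always changes, uniformly over the other three."""
    out = seq.copy()
    hit = (rng.random(seq.size) < rate) & (seq < 4)
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    out[hit] = (out[hit] + shift) % 4
    return out


def _revcomp(seq: np.ndarray) -> np.ndarray:
    comp = np.where(seq < 4, 3 - seq, seq).astype(np.uint8)
    return comp[::-1]


def expected_divergence(rates: Sequence[float]) -> float:
    """Closed-form mismatch fraction after a chain of substitution rounds.

    Each round is a uniform-replacement channel with eigenvalue
    lambda = 1 - 4r/3; the composed mismatch probability is
    (3/4) * (1 - prod(lambda_i)).
    """
    lam = 1.0
    for r in rates:
        lam *= 1 - 4 * r / 3
    return 0.75 * (1 - lam)


def _write_fasta(path: str, seqs: dict[str, np.ndarray], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, arr in seqs.items():
            fh.write(f">{name}\n")
            s = _ALPHABET[arr].tobytes().decode()
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# generator


def _islands(length: int, cfg: SimConfig) -> list[tuple[int, int]]:
    out = []
    pos = cfg.island_offset
    while pos + cfg.island_len <= length:
        out.append((pos, pos + cfg.island_len))
        pos += cfg.island_period
    return out


def _segments(origin: np.ndarray, inverted: np.ndarray) -> list[tuple[int, int, int, bool]]:
    """Maximal runs of constant (origin, inverted) as (start, end, origin, inv)."""
    n = origin.size
    change = np.nonzero((origin[1:] != origin[:-1]) | (inverted[1:] != inverted[:-1]))[0] + 1
    bounds = [0, *change.tolist(), n]
    return [
        (s, e, int(origin[s]), bool(inverted[s]))
        for s, e in zip(bounds, bounds[1:])
    ]


class _PafWriter:
    def __init__(self, path: str, seq_lens: dict[str, int]):
        self.fh = open(path, "w")
        self.lens = seq_lens

    def write(self, qname, qs, qe, strand, tname, ts, te, n_match, blen, mapq=60):
        self.fh.write(
            "\t".join(
                str(x)
                for x in (qname, self.lens[qname], qs, qe, strand,
                          tname, self.lens[tname], ts, te, n_match, blen, mapq)
            )
            + "\n"
        )

    def close(self):
        self.fh.close()


def _emit_blocks(
    writer: _PafWriter,
    ref_name: str,
    ref_seq: np.ndarray,
    scaf_name: str,
    scaf_seq: np.ndarray,
    segs: list[tuple[int, int, int, bool]],
    ref_origin: int,
    islands: list[tuple[int, int]],
    query_is_scaffold: bool,
) -> None:
    """Emit alignment blocks between one reference chromosome and one scaffold.

    Same-lineage segments are emitted whole; segments across the species
    boundary (donor vs progenitor-derived) are emitted only over conserved
    islands and skipped when inverted.  Coordinates are identical on both
    sides because every edit is in place.
    """
    for s, e, origin, inv in segs:
        if origin == ORIGIN_GAP:
            continue
        cross = (origin == ORIGIN_D) != (ref_origin == ORIGIN_D)
        if cross:
            if inv:
                continue
            pieces = [
                (max(s, a), min(e, b)) for a, b in islands if a < e and b > s
            ]
            pieces = [(a, b) for a, b in pieces if b > a]
        else:
            pieces = [(s, e)]
        for a, b in pieces:
            if inv:
                # scaffold span is the reverse complement of the source span
                tgt = _revcomp(scaf_seq[a:b])
            else:
                tgt = scaf_seq[a:b]
            n_match = int(np.sum(ref_seq[a:b] == tgt))
            strand = "-" if inv else "+"
            if query_is_scaffold:
                writer.write(scaf_name, a, b, strand, ref_name, a, b, n_match, b - a)
            else:
                writer.write(ref_name, a, b, strand, scaf_name, a, b, n_match, b - a)


def generate(config: SimConfig, outdir: str) -> Fixture:
    """Generate the full fixture set under ``outdir`` and return paths + truth."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    (ss_genome, ss_trio, ss_genes) = ss.spawn(3)
    rng = np.random.default_rng(ss_genome)

    L = config.chrom_len
    pairs = [f"chr{i + 1:02d}" for i in range(config.n_chrom_pairs)]
    islands = _islands(L, config)
    island_rate = np.full(L, config.donor_divergence)
    for a, b in islands:
        island_rate[a:b] = config.donor_divergence * config.island_factor

    anc_A: dict[str, np.ndarray] = {}
    anc_B: dict[str, np.ndarray] = {}
    donor: dict[str, np.ndarray] = {}
    for pair in pairs:
        a = _rand_seq(rng, L)
        anc_A[f"A_{pair}"] = a
        anc_B[f"B_{pair}"] = _mutate(rng, a, config.ancestor_divergence)
        donor[f"D_{pair}"] = _mutate(rng, a, island_rate)

    # base tetraploid: mutated copies of each progenitor chromosome
    tet: dict[str, np.ndarray] = {}
    origin: dict[str, np.ndarray] = {}
    inverted: dict[str, np.ndarray] = {}
    for pair in pairs:
        for sub, anc, code in (("A", anc_A[f"A_{pair}"], ORIGIN_A),
                               ("B", anc_B[f"B_{pair}"], ORIGIN_B)):
            name = f"{pair}_{sub}"
            tet[name] = _mutate(rng, anc, config.genotype_divergence)
            origin[name] = np.full(L, code, dtype=np.uint8)
            inverted[name] = np.zeros(L, dtype=bool)

    truth: dict = {"tetrasomic_tracts": [], "exchange_tracts": [],
                   "inversions": [], "introgression": None, "gaps": {}}

    for pair, s, e, anc in config.tetrasomic_tracts:
        other = "B" if anc == "A" else "A"
        src = anc_A[f"A_{pair}"] if anc == "A" else anc_B[f"B_{pair}"]
        name = f"{pair}_{other}"
        tet[name][s:e] = _mutate(rng, src[s:e], config.genotype_divergence)
        origin[name][s:e] = ORIGIN_A if anc == "A" else ORIGIN_B
        truth["tetrasomic_tracts"].append(
            {"pair": pair, "start": s, "end": e, "ancestor": anc}
        )

    for pair, s, e in config.exchange_tracts:
        na, nb = f"{pair}_A", f"{pair}_B"
        tet[na][s:e], tet[nb][s:e] = tet[nb][s:e].copy(), tet[na][s:e].copy()
        origin[na][s:e], origin[nb][s:e] = (
            origin[nb][s:e].copy(), origin[na][s:e].copy(),
        )
        truth["exchange_tracts"].append({"pair": pair, "start": s, "end": e})

    if config.introgression_tract:
        scaf, s, e = config.introgression_tract
        pair = scaf.rsplit("_", 1)[0]
        tet[scaf][s:e] = _mutate(rng, donor[f"D_{pair}"][s:e], config.genotype_divergence)
        origin[scaf][s:e] = ORIGIN_D
        truth["introgression"] = {"scaffold": scaf, "start": s, "end": e}

    for scaf, s, e in config.inversions:
        tet[scaf][s:e] = _revcomp(tet[scaf][s:e])
        inverted[scaf][s:e] = True
        truth["inversions"].append({"scaffold": scaf, "start": s, "end": e})

    for name in list(tet):
        for s, e in config.gap_spans:
            tet[name][s:e] = 4
            origin[name][s:e] = ORIGIN_GAP
        truth["gaps"][name] = [[s, e] for s, e in config.gap_spans]

    alt_name = None
    if config.alt_haplotype:
        alt_name = f"{pairs[0]}_A_alt"
        tet[alt_name] = _mutate(rng, donor[f"D_{pairs[0]}"], config.genotype_divergence)
        origin[alt_name] = np.full(L, ORIGIN_D, dtype=np.uint8)
        inverted[alt_name] = np.zeros(L, dtype=bool)
        truth["alt_haplotype"] = {"scaffold": alt_name, "pair": pairs[0]}
        truth["gaps"][alt_name] = []

    # trio parents: independent genotypes of the base tetraploid lineage
    parent1 = {n: _mutate(rng, tet[n], config.genotype_divergence)
               for n in tet if n != alt_name}
    parent2 = {n: _mutate(rng, tet[n], config.genotype_divergence)
               for n in tet if n != alt_name}

    seq_lens = {n: arr.size for coll in (anc_A, anc_B, donor, tet) for n, arr in coll.items()}

    paths = {}

    def _p(name: str) -> str:
        paths[os.path.splitext(name)[0]] = os.path.join(outdir, name)
        return paths[os.path.splitext(name)[0]]

    _write_fasta(_p("ancestorA.fasta"), anc_A)
    _write_fasta(_p("ancestorB.fasta"), anc_B)
    _write_fasta(_p("donor.fasta"), donor)
    _write_fasta(_p("tetraploid.fasta"), tet)
    _write_fasta(_p("parent1.fasta"), parent1)
    _write_fasta(_p("parent2.fasta"), parent2)

    main_scaffolds = [f"{p}_{s}" for p in pairs for s in "AB"]

    # progenitor -> tetraploid alignments (competitive ancestry + inversions)
    for anc_label, anc_seqs, code in (("A", anc_A, ORIGIN_A), ("B", anc_B, ORIGIN_B)):
        w = _PafWriter(_p(f"ancestor{anc_label}_vs_tet.paf"), seq_lens)
        for scaf in main_scaffolds:
            pair = scaf.rsplit("_", 1)[0]
            segs = _segments(origin[scaf], inverted[scaf])
            _emit_blocks(w, f"{anc_label}_{pair}", anc_seqs[f"{anc_label}_{pair}"],
                         scaf, tet[scaf], segs, code, islands, query_is_scaffold=False)
        w.close()

    # dual-reference origin alignments for the introgression pair
    origin_queries = [f"{pairs[0]}_A"] + ([alt_name] if alt_name else [])
    for label, ref_seqs, code in (("ref1", anc_A, ORIGIN_A), ("ref2", donor, ORIGIN_D)):
        prefix = "A" if label == "ref1" else "D"
        w = _PafWriter(_p(f"origin_{label}.paf"), seq_lens)
        for scaf in origin_queries:
            segs = _segments(origin[scaf], inverted[scaf])
            _emit_blocks(w, f"{prefix}_{pairs[0]}", ref_seqs[f"{prefix}_{pairs[0]}"],
                         scaf, tet[scaf], segs, code, islands, query_is_scaffold=True)
        w.close()

    # best-placement read mappings across the introgression scaffold
    read_scaf = f"{pairs[0]}_A"
    read_sources: dict[str, str] = {}
    w = _PafWriter(os.path.join(outdir, "reads_vs_tet.paf"),
                   {**seq_lens, **{f"read{i:05d}": config.read_len
                                   for i in range(L // config.read_len)}})
    paths["reads_vs_tet"] = os.path.join(outdir, "reads_vs_tet.paf")
    ref_a = anc_A[f"A_{pairs[0]}"]
    ref_d = donor[f"D_{pairs[0]}"]
    scaf_seq = tet[read_scaf]
    for i in range(L // config.read_len):
        s, e = i * config.read_len, (i + 1) * config.read_len
        frag = scaf_seq[s:e]
        if np.any(frag == 4) or np.any(inverted[read_scaf][s:e]):
            continue  # reads over gaps or inverted spans are not placed
        name = f"read{i:05d}"
        mm_a = int(np.sum(frag != ref_a[s:e]))
        mm_d = int(np.sum(frag != ref_d[s:e]))
        read_sources[name] = "recipient" if mm_a <= mm_d else "donor"
        w.write(name, 0, config.read_len, "+", read_scaf, s, e,
                config.read_len - min(mm_a, mm_d), config.read_len)
    w.close()
    truth["read_sources"] = read_sources
    truth["read_scaffold"] = read_scaf

    # genes: regularly spaced with jitter, ~2 kb, non-overlapping
    rng_genes = np.random.default_rng(ss_genes)
    gene_rows = []
    for scaf in main_scaffolds + ([alt_name] if alt_name else []):
        for k in range(L // 10_000):
            start = k * 10_000 + int(rng_genes.integers(0, 7_000))
            gene_rows.append((scaf, start, start + 2_000, f"{scaf}.g{k:04d}"))
    genes_path = _p("genes.bed")
    with open(genes_path, "w") as fh:
        for scaf, s, e, gid in gene_rows:
            fh.write(f"{scaf}\t{s}\t{e}\t{gid}\n")

    # trio VCF
    trio_truth = _write_trio_vcf(
        _p("trio.vcf"), np.random.default_rng(ss_trio), config, main_scaffolds, L
    )
    truth["trio"] = trio_truth
    truth["scaffold_lens"] = {n: int(tet[n].size) for n in tet}
    truth["main_scaffolds"] = main_scaffolds
    truth["pairs"] = pairs

    truth_path = os.path.join(outdir, "truth.json")
    paths["truth"] = truth_path
    with open(truth_path, "w") as fh:
        json.dump({"config": asdict(config), **truth}, fh, indent=1, sort_keys=True)

    return Fixture(outdir=outdir, config=config, paths=paths, truth=truth)


_BASES = "ACGT"


def _write_trio_vcf(
    path: str,
    rng: np.random.Generator,
    config: SimConfig,
    scaffolds: Sequence[str],
    length: int,
) -> dict:
    """Simulate trio genotypes and write a GT-only VCFv4.2.

    Base classes: fixed parental difference (offspring 30/40/30
    hom-ref/het/hom-alt), shared alternate (offspring and one parent carry
    alt), and uninformative; with probability ``outcross_fraction`` a site is
    instead non-parental (offspring carries an alternate absent from both
    parents).
    """
    n = config.n_trio_sites
    per = n // len(scaffolds)
    counts = {"fixed_diff": 0, "shared_alt": 0, "nonparental": 0, "uninformative": 0}
    off_classes = {"hom_ref": 0, "het": 0, "hom_alt": 0}
    lines = []
    for scaf in scaffolds:
        pos = np.sort(rng.choice(length - 1, size=per, replace=False)) + 1
        for p in pos:
            ref_i = int(rng.integers(0, 4))
            alt_i = int((ref_i + rng.integers(1, 4)) % 4)
            u = rng.random()
            if rng.random() < config.outcross_fraction:
                klass = "nonparental"
                g1 = g2 = "0/0"
                go = "0/1" if rng.random() < 0.5 else "1/1"
            elif u < 0.5:
                klass = "fixed_diff"
                if rng.random() < 0.5:
                    g1, g2 = "0/0", "1/1"
                else:
                    g1, g2 = "1/1", "0/0"
                v = rng.random()
                if v < 0.3:
                    go, oc = "0/0", "hom_ref"
                elif v < 0.7:
                    go, oc = "0/1", "het"
                else:
                    go, oc = "1/1", "hom_alt"
                off_classes[oc] += 1
            elif u < 0.75:
                klass = "shared_alt"
                # a hom-alt parent opposite a hom-ref parent would itself be a
                # fixed difference, so the alt-carrying parent is heterozygous
                # unless both parents carry the alternate
                if rng.random() < 0.5:
                    g1, g2 = ("0/1", "0/0") if rng.random() < 0.5 else ("0/0", "0/1")
                else:
                    g1, g2 = "0/1", ("1/1" if rng.random() < 0.5 else "0/1")
                go = "0/1" if rng.random() < 0.5 else "1/1"
            else:
                klass = "uninformative"
                if rng.random() < 0.5:
                    g1 = g2 = go = "0/0"
                else:
                    g1 = "0/1" if rng.random() < 0.5 else "0/0"
                    g2 = "0/0"
                    go = "0/0"
            counts[klass] += 1
            lines.append(
                f"{scaf}\t{p}\t.\t{_BASES[ref_i]}\t{_BASES[alt_i]}\t.\tPASS\t.\tGT\t{g1}\t{g2}\t{go}"
            )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for scaf in scaffolds:
            fh.write(f"##contig=<ID={scaf},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\tF1\n")
        fh.write("\n".join(lines) + "\n")
    return {"class_counts": counts, "offspring_at_fixed_diff": off_classes,
            "samples": {"p1": "P1", "p2": "P2", "off": "F1"}}


def default_fixture(outdir: str) -> Fixture:
    """The fixed published fixture used by the acceptance suite (seed 42)."""
    return generate(SimConfig(), outdir)


def load_fixture(outdir: str) -> Fixture:
    """Reload a previously generated fixture from its truth.json."""
    with open(os.path.join(outdir, "truth.json")) as fh:
        doc = json.load(fh)
    cfg_doc = doc.pop("config")
    cfg_doc["introgression_tract"] = (
        tuple(cfg_doc["introgression_tract"]) if cfg_doc["introgression_tract"] else None
    )
    for key in ("inversions", "exchange_tracts", "tetrasomic_tracts", "gap_spans"):
        cfg_doc[key] = [tuple(item) for item in cfg_doc[key]]
    config = SimConfig(**cfg_doc)
    paths = {}
    for name in ("ancestorA.fasta", "ancestorB.fasta", "donor.fasta",
                 "tetraploid.fasta", "parent1.fasta", "parent2.fasta",
                 "ancestorA_vs_tet.paf", "ancestorB_vs_tet.paf",
                 "origin_ref1.paf", "origin_ref2.paf", "reads_vs_tet.paf",
                 "genes.bed", "trio.vcf", "truth.json"):
        p = os.path.join(outdir, name)
        if os.path.exists(p):
            paths[os.path.splitext(name)[0]] = p
    return Fixture(outdir=outdir, config=config, paths=paths, truth=doc)
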