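"""Trio variant accounting: parental fixed differences and non-parental alleles.

Given a joint VCF of two parents and an offspring line, each biallelic SNP is
classified by its informativeness about inheritance: sites where the parents
are homozygous for different alleles (fixed differences) make the offspring
genotype fully informative; sites where the offspring carries an alternate
allele absent from both parents point to variation that did not originate
from the recorded cross (e.g. an inadvertent outcrossing event).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from pysam import VariantFile

from .io_core import Interval

KLASSES = ("fixed_diff", "shared_alt", "nonparental", "uninformative", "excluded")

Genotype = Optional[tuple[Optional[int], Optional[int]]]


@dataclass(frozen=True)
class TrioSite:
    """One decomposed biallelic SNP with trio genotypes and provenance class.

    Genotypes are allele-index pairs recoded against the decomposed alternate:
    0 = reference, 1 = this alternate, 2 = any other allele; None = missing.
    """

    site: Interval
    ref: str
    alt: str
    gt_p1: Genotype
    gt_p2: Genotype
    gt_off: Genotype
    klass: str


@dataclass
class TrioSummary:
    n_fixed_diff: int = 0
    n_hom_ref: int = 0
    n_het: int = 0
    n_hom_alt: int = 0
    n_missing_off: int = 0
    n_shared_alt: int = 0
    n_nonparental: int = 0
    n_uninformative: int = 0
    n_excluded: int = 0
    n_skipped_non_snp: int = 0
    excluded_chroms: list[str] = field(default_factory=list)

    @property
    def pct_hom_ref(self) -> float:
        return self._pct(self.n_hom_ref)

    @property
    def pct_het(self) -> float:
        return self._pct(self.n_het)

    @property
    def pct_hom_alt(self) -> float:
        return self._pct(self.n_hom_alt)

    def _pct(self, n: int) -> float:
        classified = self.n_fixed_diff - self.n_missing_off
        return round(100.0 * n / classified, 1) if classified else float("nan")


def _is_snp(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and alt in "ACGT"


def _recode(gt: Optional[Sequence[Optional[int]]], alt_index: int) -> Genotype:
    """Recode a raw genotype against one decomposed alternate allele."""
    if gt is None or any(a is None for a in gt) or len(gt) != 2:
        return None
    coded = tuple(0 if a == 0 else (1 if a == alt_index else 2) for a in gt)
    return coded  # type: ignore[return-value]


def _classify_site(gt_p1: Genotype, gt_p2: Genotype, gt_off: Genotype) -> str:
    parents = (gt_p1, gt_p2)
    # strictly biallelic configuration required for a fixed difference
    if (
        gt_p1 is not None and gt_p2 is not None
        and gt_p1[0] == gt_p1[1] and gt_p2[0] == gt_p2[1]
        and gt_p1[0] != gt_p2[0]
        and {gt_p1[0], gt_p2[0]} == {0, 1}
        and (gt_off is None or 2 not in gt_off)
    ):
        return "fixed_diff"
    if gt_off is not None and 1 in gt_off:
        p1_alt = gt_p1 is not None and 1 in gt_p1
        p2_alt = gt_p2 is not None and 1 in gt_p2
        if not p1_alt and not p2_alt and gt_p1 is not None and gt_p2 is not None:
            return "nonparental"
        if p1_alt or p2_alt:
            return "shared_alt"
    return "uninformative"


def classify_trio(
    vcf: str,
    p1: str,
    p2: str,
    off: str,
    exclude: Sequence[str] = (),
    min_gq: Optional[int] = None,
    min_dp: Optional[int] = None,
) -> tuple[list[TrioSite], int]:
    """Classify every SNP in a joint VCF by trio provenance.

    Multi-allelic sites are decomposed per alternate allele; a site is a fixed
    difference only under a strictly biallelic configuration.  Sites on
    chromosomes in ``exclude`` are labeled ``excluded``; sites failing the
    optional GQ/DP floors in any sample are ``uninformative``.  Returns the
    site list and the number of skipped non-SNP records.
    """
    vf = VariantFile(vcf)
    samples = list(vf.header.samples)
    for name in (p1, p2, off):
        if name not in samples:
            raise KeyError(f"sample {name!r} not in VCF (has {samples})")
    exclude_set = set(exclude)
    sites: list[TrioSite] = []
    n_skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        for ai, alt in enumerate(alts, start=1):
            if not _is_snp(rec.ref, alt):
                n_skipped += 1
                continue
            pos0 = rec.pos - 1  # VCF POS is 1-based
            site = Interval(rec.chrom, pos0, pos0 + 1)
            gts = {}
            qual_fail = False
            for name in (p1, p2, off):
                smp = rec.samples[name]
                gts[name] = _recode(smp.get("GT"), ai)
                if min_gq is not None and (smp.get("GQ") or 0) < min_gq:
                    qual_fail = True
                if min_dp is not None and (smp.get("DP") or 0) < min_dp:
                    qual_fail = True
            if rec.chrom in exclude_set:
                klass = "excluded"
            elif qual_fail:
                klass = "uninformative"
            else:
                klass = _classify_site(gts[p1], gts[p2], gts[off])
            sites.append(
                TrioSite(site, rec.ref, alt, gts[p1], gts[p2], gts[off], klass)
            )
    return sites, n_skipped


def summarize_trio(sites: Sequence[TrioSite]) -> TrioSummary:
    """Tally fixed-difference offspring classes and the remaining site classes."""
    s = TrioSummary()
    excluded_chroms = set()
    for site in sites:
        if site.klass == "fixed_diff":
            s.n_fixed_diff += 1
            gt = site.gt_off
            if gt is None:
                s.n_missing_off += 1
                continue
            # recode relative to the parental fixed-difference alt allele
            n_alt = sum(a == 1 for a in gt)
            if n_alt == 0:
                s.n_hom_ref += 1
            elif n_alt == 1:
                s.n_het += 1
            else:
                s.n_hom_alt += 1
        elif site.klass == "shared_alt":
            s.n_shared_alt += 1
        elif site.klass == "nonparental":
            s.n_nonparental += 1
        elif site.klass == "excluded":
            s.n_excluded += 1
            excluded_chroms.add(site.site.seq_name)
        else:
            s.n_uninformative += 1
    s.excluded_chroms = sorted(excluded_chroms)
    return s


def summary_table(s: TrioSummary) -> pd.DataFrame:
    rows = [
        ("parental_fixed_differences", s.n_fixed_diff, float("nan")),
        ("offspring_hom_ref_at_fixed_diff", s.n_hom_ref, s.pct_hom_ref),
        ("offspring_het_at_fixed_diff", s.n_het, s.pct_het),
        ("offspring_hom_alt_at_fixed_diff", s.n_hom_alt, s.pct_hom_alt),
        ("offspring_and_parent_share_alt", s.n_shared_alt, float("nan")),
        ("nonparental_allele_sites", s.n_nonparental, float("nan")),
    ]
    return pd.DataFrame(rows, columns=["statistic", "count", "percent"])
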