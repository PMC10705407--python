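"""Population-variation profiles around splice sites.

SNP rates are the fraction of sites carrying a qualifying single-nucleotide
variant at a given transcript-orientation shift from the canonical
dinucleotide.  Only variants with at least one homozygous-alternate sample
qualify by default — a homozygous change at a functional splice site is
strongly deleterious, so its presence in a healthy population argues against
purifying selection at that site.  Clinical-variant overlap counts sites
whose canonical dinucleotide carries a pathogenic or likely-pathogenic
variant, and allele-frequency summaries contrast homozygous-SNP frequencies
between label classes.

Variant coordinates are converted from VCF 1-based to the internal 0-based
convention on ingestion; multi-allelic records are split into per-allele
SNVs before filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from splicecons.annotation import SpliceSite

DEFAULT_WINDOW = tuple(range(-4, 8))


@dataclass(frozen=True)
class VariantView:
    """One SNV allele with its population and clinical annotations."""

    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    n_hom: int
    af: float
    clnsig: tuple[str, ...] = ()


def _as_tuple(value) -> tuple:
    if value is None:
        return ()
    if isinstance(value, (list, tuple, np.ndarray)):
        return tuple(value)
    return (value,)


def load_variants(
    vcf_path,
    af_key: str = "AF",
    hom_key: str = "nhomalt",
    clnsig_key: str = "CLNSIG",
) -> list[VariantView]:
    """Read SNV alleles from a VCF, splitting multi-allelic records.

    INFO key names are configurable to accommodate different population
    databases; missing keys default to ``AF=0`` and ``n_hom=0``.
    """
    out = []
    for record in VCF(str(vcf_path)):
        afs = _as_tuple(record.INFO.get(af_key))
        homs = _as_tuple(record.INFO.get(hom_key))
        clnsig_raw = record.INFO.get(clnsig_key)
        clnsig = tuple(str(clnsig_raw).split("|")) if clnsig_raw is not None else ()
        for i, alt in enumerate(record.ALT):
            if len(record.REF) != 1 or len(alt) != 1:
                continue
            af = float(afs[i]) if i < len(afs) else 0.0
            n_hom = int(homs[i]) if i < len(homs) else 0
            out.append(
                VariantView(
                    contig=record.CHROM,
                    position=record.POS - 1,
                    ref=record.REF,
                    alt=alt,
                    n_hom=n_hom,
                    af=af,
                    clnsig=clnsig,
                )
            )
    return out


class VariantIndex:
    """Positional index over SNV alleles."""

    def __init__(self, variants: list[VariantView]):
        self._by_pos: dict[tuple[str, int], list[VariantView]] = {}
        for v in variants:
            self._by_pos.setdefault((v.contig, v.position), []).append(v)

    def at(self, contig: str, position: int) -> list[VariantView]:
        return self._by_pos.get((contig, position), [])


def snp_rate_profile(
    sites: list[SpliceSite],
    variants: VariantIndex | list[VariantView],
    window: tuple[int, ...] = DEFAULT_WINDOW,
    require_hom: int = 1,
) -> dict[int, float]:
    """Per-shift fraction of sites with >=1 qualifying SNV.

    Shifts follow transcript orientation (0 and 1 are the canonical
    dinucleotide); a site counts at most once per shift no matter how many
    alleles overlap it.
    """
    if not isinstance(variants, VariantIndex):
        variants = VariantIndex(variants)
    rates = {}
    for shift in window:
        n_hit = 0
        for site in sites:
            pos = site.position_at(shift)
            if any(v.n_hom >= require_hom for v in variants.at(site.contig, pos)):
                n_hit += 1
        rates[shift] = n_hit / len(sites) if sites else 0.0
    return rates


_PATHOGENIC_TERMS = ("pathogenic", "likely_pathogenic")


def is_pathogenic(variant: VariantView) -> bool:
    """Case-insensitive match on pathogenic/likely-pathogenic, excluding
    conflicting-interpretation records."""
    for sig in variant.clnsig:
        s = sig.lower().replace(" ", "_")
        if "conflicting" in s:
            continue
        if any(term in s for term in _PATHOGENIC_TERMS):
            return True
    return False


def pathogenic_overlap(
    site_groups: dict[tuple[str, str, str], list[SpliceSite]],
    variants: VariantIndex | list[VariantView],
) -> pd.DataFrame:
    """Counts of sites with a pathogenic SNV at their canonical dinucleotide.

    ``site_groups`` maps (dataset, label, kind) to its sites; the percentage
    is relative to the group size.  Each site counts at most once.
    """
    if not isinstance(variants, VariantIndex):
        variants = VariantIndex(variants)
    rows = []
    for (dataset, label, kind), sites in site_groups.items():
        n = 0
        for site in sites:
            hit = False
            for shift in (0, 1):
                pos = site.position_at(shift)
                if any(is_pathogenic(v) for v in variants.at(site.contig, pos)):
                    hit = True
                    break
            n += hit
        rows.append(
            {
                "dataset": dataset,
                "label": label,
                "kind": kind,
                "n_sites": len(sites),
                "n_pathogenic": n,
                "percent": 100.0 * n / len(sites) if sites else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def hom_af_distribution(
    site_groups: dict[str, list[SpliceSite]],
    variants: VariantIndex | list[VariantView],
    require_hom: int = 1,
) -> pd.DataFrame:
    """Median and IQR of homozygous-SNV allele frequencies at canonical
    dinucleotides, per site group (e.g. label class)."""
    if not isinstance(variants, VariantIndex):
        variants = VariantIndex(variants)
    rows = []
    for group, sites in site_groups.items():
        afs = []
        for site in sites:
            for shift in (0, 1):
                pos = site.position_at(shift)
                afs.extend(
                    v.af for v in variants.at(site.contig, pos) if v.n_hom >= require_hom
                )
        if afs:
            arr = np.asarray(afs)
            q1, med, q3 = np.percentile(arr, [25, 50, 75])
            rows.append(
                {
                    "group": group,
                    "n_variants": len(afs),
                    "median_af": float(med),
                    "iqr_af": float(q3 - q1),
                }
            )
        else:
            rows.append(
                {
                    "group": group,
                    "n_variants": 0,
                    "median_af": float("nan"),
                    "iqr_af": float("nan"),
                }
            )
    return pd.DataFrame(rows)
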