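"""Variant-table processing: parsing, final-processing filters, and
mutation-spectrum classification.

The trajectory table is a pandas DataFrame with one row per variant, fixed
annotation columns (``mutation_id, chromosome, position, ref, alt, class,
gene`` and optionally ``effect``) and one frequency column per sampled
generation named ``g<generation>`` with values in [0, 1] (NaN where the time
point was not sequenced for that variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation

__all__ = [
    "freq_columns", "read_trajectories", "write_trajectories", "read_vcf",
    "subtract_ancestor", "filter_subtelomeric", "filter_static_trajectories",
    "filter_for_haplotyping", "adjust_heterozygous_frequencies",
    "classify_mutations", "SpectrumSummary",
]

ANNOT_COLUMNS = ["mutation_id", "chromosome", "position", "ref", "alt",
                 "class", "gene"]


def freq_columns(table: pd.DataFrame) -> list[str]:
    """Frequency columns (``g<generation>``) in increasing generation order."""
    cols = [c for c in table.columns if c.startswith("g") and c[1:].isdigit()]
    return sorted(cols, key=lambda c: int(c[1:]))


def read_trajectories(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("mutation_id", "chromosome", "position") if c not in table]
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    if "gene" in table:
        table["gene"] = table["gene"].fillna("")
    return table


def write_trajectories(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_vcf(path: str, sample_generations: list[int],
             af_tag: str = "AF") -> pd.DataFrame:
    """Read per-time-point allele frequencies from a multi-sample VCF.

    Samples are taken in column order and mapped onto ``sample_generations``;
    frequencies come from the FORMAT tag ``af_tag`` or, failing that, from
    allelic depths (``AD``).
    """
    from cyvcf2 import VCF
    vcf = VCF(path)
    if len(vcf.samples) != len(sample_generations):
        raise ValueError(f"VCF has {len(vcf.samples)} samples but "
                         f"{len(sample_generations)} generations were given")
    rows = []
    for i, rec in enumerate(vcf):
        for alt in rec.ALT:
            row = {
                "mutation_id": rec.ID or f"v{i:05d}",
                "chromosome": rec.CHROM, "position": rec.POS,
                "ref": rec.REF, "alt": alt,
                "class": "SNP" if len(rec.REF) == 1 and len(alt) == 1 else "indel",
                "gene": (rec.INFO.get("GENE") or ""),
            }
            try:
                af = rec.format(af_tag)
                freqs = np.asarray(af, dtype=float).reshape(len(vcf.samples), -1)[:, 0]
            except (KeyError, TypeError):
                ad = np.asarray(rec.format("AD"), dtype=float)
                tot = ad.sum(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    freqs = np.where(tot > 0, ad[:, 1] / tot, np.nan)
            for g, f in zip(sample_generations, freqs):
                row[f"g{g}"] = float(f) if np.isfinite(f) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def _site_key(table: pd.DataFrame) -> pd.Series:
    return (table["chromosome"].astype(str) + ":" + table["position"].astype(str)
            + ":" + table["ref"].astype(str) + ">" + table["alt"].astype(str))


def subtract_ancestor(table: pd.DataFrame, ancestor: pd.DataFrame) -> pd.DataFrame:
    """Drop variants already present in the ancestral strain (site-key match
    on chromosome, position, ref and alt)."""
    keep = ~_site_key(table).isin(set(_site_key(ancestor)))
    return table[keep].reset_index(drop=True)


def filter_subtelomeric(table: pd.DataFrame, annotation: GenomeAnnotation,
                        margin: int = 15_000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove variants within ``margin`` bp of either chromosome end.

    Positions are 1-based; a variant is removed when ``position <= margin``
    or ``position > length - margin``. Chromosomes shorter than twice the
    margin lose all their variants. Returns ``(kept, removed)``.
    """
    unknown = set(table["chromosome"]) - set(annotation.chrom_lengths)
    if unknown:
        raise ValueError(f"unknown chromosome(s): {sorted(unknown)}")
    lengths = table["chromosome"].map(annotation.chrom_lengths)
    pos = table["position"]
    removed = (pos <= margin) | (pos > lengths - margin)
    return (table[~removed].reset_index(drop=True),
            table[removed].reset_index(drop=True))


def filter_static_trajectories(table: pd.DataFrame,
                               min_change: float = 0.10,
                               relative: bool = False) -> pd.DataFrame:
    """Keep variants whose frequency changed by more than ``min_change``
    during the experiment (strict inequality; absolute range by default,
    range/max when ``relative``)."""
    cols = freq_columns(table)
    if len(cols) < 2:
        raise ValueError("need at least 2 frequency observations per record")
    freqs = table[cols].to_numpy(dtype=float)
    if np.isnan(freqs).all(axis=1).any():
        raise ValueError("records with all-missing frequencies are not allowed")
    rng = np.nanmax(freqs, axis=1) - np.nanmin(freqs, axis=1)
    if relative:
        with np.errstate(invalid="ignore", divide="ignore"):
            rng = np.where(np.nanmax(freqs, axis=1) > 0,
                           rng / np.nanmax(freqs, axis=1), 0.0)
    # strict "> min_change", robust to float rounding at the boundary
    return table[rng > min_change + 1e-12].reset_index(drop=True)


def _zygosity_pivot(clone_table: pd.DataFrame) -> pd.DataFrame:
    return clone_table.pivot_table(index="mutation_id", columns="clone",
                                   values="zygosity", aggfunc="first")


def filter_for_haplotyping(table: pd.DataFrame,
                           clone_table: pd.DataFrame | None = None,
                           min_peak: float = 0.2) -> pd.DataFrame:
    """Pre-clustering exclusions: multi-allelic sites, variants with mixed
    zygosity across sequenced clones, and variants that never reach
    ``min_peak`` frequency."""
    site = table["chromosome"].astype(str) + ":" + table["position"].astype(str)
    multi = site.map(site.value_counts()) > 1
    keep = ~multi

    if clone_table is not None and not clone_table.empty:
        zyg = _zygosity_pivot(clone_table)
        mixed = set()
        for mid, row in zyg.iterrows():
            states = set(row.dropna())
            if "homozygous" in states and "heterozygous" in states:
                mixed.add(mid)
        keep &= ~table["mutation_id"].isin(mixed)

    cols = freq_columns(table)
    peak = table[cols].to_numpy(dtype=float)
    peak = np.nanmax(np.where(np.isnan(peak), -np.inf, peak), axis=1)
    keep &= peak >= min_peak
    return table[keep].reset_index(drop=True)


def adjust_heterozygous_frequencies(table: pd.DataFrame,
                                    clone_table: pd.DataFrame,
                                    tolerance: float = 0.10
                                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Report cell-level frequencies for heterozygous diploid mutations.

    Where a variant is heterozygous in every sequenced clone of a time point
    and its population allele frequency lies within ``tolerance`` of 0.5,
    the frequency is doubled (capped at 1): every cell carries one copy.
    Returns ``(adjusted table, log of adjustments)``.
    """
    table = table.copy()
    cols = freq_columns(table)
    zyg = _zygosity_pivot(clone_table) if not clone_table.empty else pd.DataFrame()
    gen_of_clone = (clone_table.drop_duplicates("clone")
                    .set_index("clone")["generation"].to_dict()
                    if not clone_table.empty else {})
    log_rows = []
    for idx, row in table.iterrows():
        mid = row["mutation_id"]
        for col in cols:
            g = int(col[1:])
            af = row[col]
            if not np.isfinite(af) or abs(af - 0.5) > tolerance:
                continue
            clones_at_g = [c for c, cg in gen_of_clone.items() if cg == g]
            if not clones_at_g or mid not in zyg.index:
                continue
            states = [zyg.loc[mid, c] for c in clones_at_g]
            if all(s == "heterozygous" for s in states):
                table.at[idx, col] = min(1.0, 2.0 * af)
                log_rows.append({"mutation_id": mid, "generation": g,
                                 "allele_frequency": af,
                                 "cell_frequency": min(1.0, 2.0 * af)})
    return table, pd.DataFrame(log_rows, columns=["mutation_id", "generation",
                                                  "allele_frequency",
                                                  "cell_frequency"])


@dataclass
class SpectrumSummary:
    """Mutation-spectrum counts over distinct sites."""
    n_sites: int
    by_class: dict[str, int]
    coding_by_class: dict[str, dict[str, int]]   # class -> {coding, non-coding}
    effect_coding_snps: dict[str, int]           # synonymous / non-synonymous

    def fraction(self, mclass: str) -> float:
        return self.by_class.get(mclass, 0) / self.n_sites if self.n_sites else 0.0


def classify_mutations(table: pd.DataFrame,
                       annotation: GenomeAnnotation) -> SpectrumSummary:
    """Count distinct mutated sites by class (SNP/indel), genomic context
    (coding = overlapping a gene interval) and, for coding SNPs, by the
    provided effect labels."""
    if table.empty:
        return SpectrumSummary(0, {}, {}, {})
    sites = table.drop_duplicates(subset=["chromosome", "position", "ref", "alt"])
    chroms = sites["chromosome"].to_numpy(dtype=object)
    pos = sites["position"].to_numpy(dtype=int)
    genes = annotation.genes_at(chroms, pos)
    coding = np.array([g != "" for g in genes])
    cls = sites["class"].to_numpy(dtype=object)
    by_class: dict[str, int] = {}
    coding_by_class: dict[str, dict[str, int]] = {}
    for c in np.unique(cls):
        sel = cls == c
        by_class[str(c)] = int(sel.sum())
        coding_by_class[str(c)] = {"coding": int((sel & coding).sum()),
                                   "non-coding": int((sel & ~coding).sum())}
    effects: dict[str, int] = {}
    if "effect" in sites.columns:
        snp_coding = (cls == "SNP") & coding
        for eff, n in sites.loc[snp_coding, "effect"].value_counts().items():
            if str(eff) not in ("", "NA", "nan"):
                effects[str(eff)] = int(n)
    return SpectrumSummary(n_sites=len(sites), by_class=by_class,
                           coding_by_class=coding_by_class,
                           effect_coding_snps=effects)
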