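"""Reading, QC, harmonization and filtering of GWAS summary statistics.

Input files are whitespace/tab-delimited tables with a recognisable header
(case-insensitive synonyms accepted, e.g. SNP/RSID, A1/EFFECT_ALLELE).  QC
drops rows with missing mandatory fields, invalid p-values, and chi-square
outliers above max(80, N/1000) — the convention of the LDSC software — and
records every count.  Harmonization aligns two traits to a reference SNP
list, flipping Z signs for swapped alleles and dropping strand-ambiguous
(A/T, C/G) SNPs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SumStats",
    "AlignedPair",
    "read_sumstats",
    "harmonize",
    "exclude_significant_regions",
]

MANDATORY = ["snp_id", "a1", "a2", "z", "p", "n"]

_SYNONYMS = {
    "snp_id": {"snp", "rsid", "rs_id", "markername", "id"},
    "chrom": {"chr", "chrom", "chromosome"},
    "bp": {"bp", "pos", "position", "base_pair_location"},
    "a1": {"a1", "effect_allele", "allele1", "ea"},
    "a2": {"a2", "other_allele", "allele2", "oa", "non_effect_allele"},
    "z": {"z", "zscore", "z_score", "stat"},
    "p": {"p", "pval", "p_value", "pvalue"},
    "n": {"n", "samplesize", "sample_size", "neff"},
    "beta": {"beta", "b", "effect", "log_odds"},
    "se": {"se", "stderr", "standard_error"},
}

AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SumStats:
    """Per-SNP association records for one trait.

    Wraps a DataFrame with canonical columns snp_id, chrom, bp, a1, a2, z,
    p, n (plus beta/se when present).  `qc` records what the reader dropped.
    """

    df: pd.DataFrame
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY if c not in self.df.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        if self.df["snp_id"].duplicated().any():
            raise ValueError("duplicated snp_id in SumStats")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def z(self) -> np.ndarray:
        return self.df["z"].to_numpy(dtype=float)

    @property
    def p(self) -> np.ndarray:
        return self.df["p"].to_numpy(dtype=float)

    @property
    def n(self) -> np.ndarray:
        return self.df["n"].to_numpy(dtype=float)

    @property
    def snp_id(self) -> pd.Series:
        return self.df["snp_id"]

    def write(self, path) -> None:
        out = self.df.rename(
            columns={
                "snp_id": "SNP", "chrom": "CHR", "bp": "BP",
                "a1": "A1", "a2": "A2", "z": "Z", "p": "P", "n": "N",
            }
        )
        out.to_csv(path, sep="\t", index=False)


@dataclass
class AlignedPair:
    """Two traits restricted to shared, allele-harmonized SNPs in reference order."""

    ss1: SumStats
    ss2: SumStats
    flipped1: np.ndarray
    flipped2: np.ndarray
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ss1.snp_id.reset_index(drop=True).equals(
            self.ss2.snp_id.reset_index(drop=True)
        ):
            raise ValueError("aligned traits must share an identical snp_id sequence")

    def __len__(self) -> int:
        return len(self.ss1)


def _canonicalize_header(columns) -> dict:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        for canon, names in _SYNONYMS.items():
            if key == canon or key in names:
                if canon not in mapping.values():
                    mapping[col] = canon
                break
    return mapping


def read_sumstats(path, chi2_cap: float | None = None) -> SumStats:
    """Read and QC one summary-statistics file.

    Z is reconstructed as beta/se when absent; rows with missing mandatory
    fields, p outside (0,1], or chi-square above max(80, N/1000) (override
    with chi2_cap) are dropped and counted in the returned `qc` dict.
    """
    raw = pd.read_csv(path, sep=r"\s+")
    mapping = _canonicalize_header(raw.columns)
    df = raw.rename(columns=mapping)
    have = set(df.columns)
    needed = {"snp_id", "a1", "a2", "p", "n"}
    if "z" not in have and not {"beta", "se"} <= have:
        needed = needed | {"z (or beta+se)"}
    missing = sorted(needed - have)
    if missing:
        raise ValueError(
            f"unrecognizable header in {path}: missing columns {missing} "
            f"(found {sorted(raw.columns)})"
        )

    qc = {"n_input": len(df)}
    if "z" not in df.columns:
        df["z"] = df["beta"] / df["se"]
    elif {"beta", "se"} <= set(df.columns):
        recon = df["beta"] / df["se"]
        fill = df["z"].isna() & recon.notna()
        df.loc[fill, "z"] = recon[fill]

    before = len(df)
    df = df.dropna(subset=[c for c in MANDATORY if c in df.columns])
    qc["dropped_missing"] = before - len(df)

    bad_p = ~((df["p"] > 0) & (df["p"] <= 1))
    if bad_p.any():
        warnings.warn(f"{int(bad_p.sum())} rows with p outside (0,1] dropped")
    qc["dropped_bad_p"] = int(bad_p.sum())
    df = df[~bad_p]

    cap = chi2_cap if chi2_cap is not None else np.maximum(80.0, df["n"] / 1000.0)
    outlier = df["z"] ** 2 > cap
    qc["dropped_chi2_outlier"] = int(outlier.sum())
    df = df[~outlier]

    dup = df["snp_id"].duplicated()
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicated rsIDs: keeping first occurrence")
    qc["dropped_duplicate"] = int(dup.sum())
    df = df[~dup]

    for col in ("a1", "a2"):
        df[col] = df[col].str.upper()
    df = df.reset_index(drop=True)
    logger.info(
        "read %s: %d rows kept (%d missing, %d bad p, %d chi2 outliers, %d duplicates dropped)",
        path, len(df), qc["dropped_missing"], qc["dropped_bad_p"],
        qc["dropped_chi2_outlier"], qc["dropped_duplicate"],
    )
    return SumStats(df=df, qc=qc)


def harmonize(ss1: SumStats, ss2: SumStats, reference: pd.DataFrame) -> AlignedPair:
    """Align two traits to a reference (columns SNP/snp_id, A1/a1, A2/a2, in panel order).

    SNPs absent from either trait or the reference are dropped; A1/A2 swaps
    relative to the reference flip the Z sign; strand-ambiguous and
    allele-mismatched SNPs are dropped.  Raises if no SNP survives.
    """
    ref = reference.rename(columns=_canonicalize_header(reference.columns)).copy()
    if ref["snp_id"].duplicated().any():
        raise ValueError("reference SNP ids must be unique")
    ref["_order"] = np.arange(len(ref))

    def _one(ss: SumStats):
        merged = ref.merge(ss.df, on="snp_id", suffixes=("_ref", ""))
        same = (merged["a1"] == merged["a1_ref"]) & (merged["a2"] == merged["a2_ref"])
        swap = (merged["a1"] == merged["a2_ref"]) & (merged["a2"] == merged["a1_ref"])
        ambig = [
            (x, y) in AMBIGUOUS
            for x, y in zip(merged["a1_ref"], merged["a2_ref"])
        ]
        ambig = np.asarray(ambig)
        keep = (same | swap) & ~ambig
        merged = merged[keep].copy()
        flipped = swap[keep].to_numpy()
        merged["_flipped"] = flipped
        merged.loc[flipped, "z"] = -merged.loc[flipped, "z"]
        merged.loc[flipped, ["a1", "a2"]] = merged.loc[flipped, ["a2", "a1"]].to_numpy()
        if "beta" in merged.columns:
            merged.loc[flipped, "beta"] = -merged.loc[flipped, "beta"]
        stats_d = {
            "dropped_unmatched": len(ss) - int((same | swap).sum()),
            "dropped_ambiguous": int((ambig & (same | swap)).sum()),
            "n_flipped": int(flipped.sum()),
        }
        return merged, stats_d

    m1, r1 = _one(ss1)
    m2, r2 = _one(ss2)
    shared = set(m1["snp_id"]) & set(m2["snp_id"])
    m1 = m1[m1["snp_id"].isin(shared)].sort_values("_order")
    m2 = m2[m2["snp_id"].isin(shared)].sort_values("_order")
    if len(m1) == 0:
        raise ValueError("no SNPs survive harmonization")

    f1 = m1.pop("_flipped").to_numpy()
    f2 = m2.pop("_flipped").to_numpy()
    cols = [c for c in m1.columns if not c.endswith("_ref") and c != "_order"]
    out1 = SumStats(df=m1[cols].reset_index(drop=True), qc=dict(ss1.qc))
    out2 = SumStats(df=m2[cols].reset_index(drop=True), qc=dict(ss2.qc))
    report = {"trait1": r1, "trait2": r2, "n_aligned": len(out1)}
    return AlignedPair(ss1=out1, ss2=out2, flipped1=f1, flipped2=f2, report=report)


def exclude_significant_regions(
    ss: SumStats, p_thresh: float = 5e-8, window_kb: float = 500.0
):
    """Drop every SNP within window_kb of a genome-wide-significant SNP.

    Mirrors the heritability-attenuation analysis: after removing significant
    loci (p < p_thresh) and their neighbourhoods, how much h2 remains.
    Returns (filtered SumStats, fraction of SNPs removed).
    """
    if not 0 < p_thresh < 1:
        raise ValueError("p_thresh must be in (0, 1)")
    df = ss.df
    if "chrom" not in df.columns or "bp" not in df.columns:
        raise ValueError("exclude_significant_regions needs chrom and bp columns")
    window = window_kb * 1000.0
    drop = np.zeros(len(df), dtype=bool)
    for _, sub in df.groupby("chrom", sort=False):
        pos = sub["bp"].to_numpy(dtype=float)
        sig = pos[sub["p"].to_numpy() < p_thresh]
        if len(sig) == 0:
            continue
        order = np.argsort(pos)
        sorted_pos = pos[order]
        hit = np.zeros(len(sub), dtype=bool)
        for s in sig:
            lo = np.searchsorted(sorted_pos, s - window, side="left")
            hi = np.searchsorted(sorted_pos, s + window, side="right")
            hit[order[lo:hi]] = True
        drop[sub.index.to_numpy()] = hit
    removed_fraction = float(drop.mean())
    kept = df[~drop].reset_index(drop=True)
    if len(kept) == 0:
        warnings.warn("all SNPs fall in significant regions; result is empty")
        return _empty_like(ss, removed_fraction), removed_fraction
    qc = dict(ss.qc)
    qc["removed_significant_fraction"] = removed_fraction
    return SumStats(df=kept, qc=qc), removed_fraction


def _empty_like(ss: SumStats, removed_fraction: float) -> SumStats:
    qc = dict(ss.qc)
    qc["removed_significant_fraction"] = removed_fraction
    return SumStats(df=ss.df.iloc[0:0].reset_index(drop=True), qc=qc)


def zp_consistent(ss: SumStats, tol: float = 1e-4) -> bool:
    """Check |p - two-sided normal tail of z| <= tol for every row."""
    expected = 2.0 * stats.norm.sf(np.abs(ss.z))
    return bool(np.all(np.abs(ss.p - expected) <= tol))
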