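"""Reading and writing the formats the imputation workflow touches.

Covers the phased reference panel (VCF with phased GT), target genotype
likelihoods (VCF with GL or PL), truth genotypes (VCF with GT), the genetic
map (plain text, HapMap- or PLINK-style), and the imputed output (VCF with
GT/GP/DS).  All VCF I/O goes through pysam; coordinates are 1-based as in
VCF.

Sites are matched between files by the exact key (chromosome, position,
ref, alt).  Allele-swapped or strand-flipped records are dropped and
counted, never reconciled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "ReferencePanel",
    "GeneticMap",
    "LikelihoodMatrix",
    "UNIFORM_GL",
    "read_reference_panel",
    "read_target_likelihoods",
    "read_truth_genotypes",
    "read_genetic_map",
    "write_imputed_vcf",
    "write_panel_vcf",
    "write_truth_vcf",
    "write_gl_vcf",
    "write_genetic_map",
]

#: Literal likelihood assigned to each genotype at unobserved sites.
UNIFORM_GL = 0.3333

_BASES = frozenset("ACGT")


@dataclass
class ReferencePanel:
    """H phased reference haplotypes over M biallelic SNP sites."""

    chrom: str
    positions: np.ndarray  # (M,) int64, 1-based, strictly increasing
    ref_alleles: np.ndarray  # (M,) single-character strings
    alt_alleles: np.ndarray  # (M,) single-character strings
    haplotypes: np.ndarray  # (H, M) uint8 allele codes in {0, 1}
    sample_names: list[str] = field(default_factory=list)
    skipped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.ref_alleles = np.asarray(self.ref_alleles)
        self.alt_alleles = np.asarray(self.alt_alleles)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D (H, M) matrix")
        H, M = self.haplotypes.shape
        if H < 2 or M < 1:
            raise ValueError("panel needs H >= 2 haplotypes and M >= 1 sites")
        if self.positions.shape[0] != M:
            raise ValueError("positions must have one entry per site")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes.max(initial=0) > 1:
            raise ValueError("haplotype allele codes must be 0 or 1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def alt_frequency(self) -> np.ndarray:
        """Per-site alternative-allele frequency within the panel."""
        return self.haplotypes.mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency, min(f, 1-f)."""
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def site_key(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.positions,
                "ref": self.ref_alleles,
                "alt": self.alt_alleles,
            }
        )


@dataclass
class GeneticMap:
    """Monotone mapping from physical position (bp) to cumulative cM."""

    positions: np.ndarray
    cumulative_cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cumulative_cm = np.asarray(self.cumulative_cm, dtype=float)
        if self.positions.shape[0] < 2:
            raise ValueError("genetic map needs at least 2 entries")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cumulative_cm) < 0):
            raise ValueError("cumulative cM must be non-decreasing")

    def interpolate(self, positions) -> np.ndarray:
        """Cumulative cM at arbitrary physical positions.

        Linear interpolation between map knots; positions beyond the map
        ends are extrapolated at the nearest flanking interval's rate
        (never negative).  Non-decreasing for sorted queries.
        """
        q = np.asarray(positions, dtype=float)
        out = np.interp(q, self.positions, self.cumulative_cm)
        mp, mc = self.positions.astype(float), self.cumulative_cm
        left_rate = max((mc[1] - mc[0]) / (mp[1] - mp[0]), 0.0)
        right_rate = max((mc[-1] - mc[-2]) / (mp[-1] - mp[-2]), 0.0)
        below = q < mp[0]
        above = q > mp[-1]
        out = np.where(below, mc[0] - (mp[0] - q) * left_rate, out)
        out = np.where(above, mc[-1] + (q - mp[-1]) * right_rate, out)
        if out.ndim == 0:
            return float(out)
        return out


@dataclass
class LikelihoodMatrix:
    """Per-site genotype likelihood triplets L(0), L(1), L(2) for one sample.

    Rows are linear-scale likelihoods (not log); the model is invariant to
    positive rescaling of any row.  ``observed`` flags whether the site
    carried data in the input; unobserved rows hold the uniform triplet.
    """

    likelihoods: np.ndarray  # (M, 3) floats in [0, 1]
    observed: np.ndarray  # (M,) bool
    n_unmatched_target_records: int = 0
    n_missing_truth: int = 0

    def __post_init__(self) -> None:
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.likelihoods.ndim != 2 or self.likelihoods.shape[1] != 3:
            raise ValueError("likelihoods must be an (M, 3) matrix")
        if self.observed.shape[0] != self.likelihoods.shape[0]:
            raise ValueError("observed flags must have one entry per site")
        if np.any(self.likelihoods < 0) or np.any(self.likelihoods > 1):
            raise ValueError("likelihood entries must lie in [0, 1]")
        if np.any(self.likelihoods.max(axis=1) <= 0):
            raise ValueError("every likelihood row needs a positive entry")

    @property
    def n_sites(self) -> int:
        return self.likelihoods.shape[0]

    def rescaled(self) -> "LikelihoodMatrix":
        """Copy with each row rescaled so its maximum entry is 1."""
        scaled = self.likelihoods / self.likelihoods.max(axis=1, keepdims=True)
        return LikelihoodMatrix(
            scaled,
            self.observed.copy(),
            self.n_unmatched_target_records,
            self.n_missing_truth,
        )


def _region_match(chrom: str, pos: int, region: str | None) -> bool:
    if region is None:
        return True
    if ":" not in region:
        return chrom == region
    rchrom, span = region.split(":", 1)
    start, end = (int(x) for x in span.replace(",", "").split("-"))
    return chrom == rchrom and start <= pos <= end


def _is_biallelic_snp(rec) -> bool:
    if rec.alts is None or len(rec.alts) != 1:
        return False
    return (
        len(rec.ref) == 1
        and len(rec.alts[0]) == 1
        and rec.ref.upper() in _BASES
        and rec.alts[0].upper() in _BASES
    )


def read_reference_panel(vcf_path, region: str | None = None) -> ReferencePanel:
    """Load a phased reference panel from VCF.

    Keeps biallelic SNP records only; multiallelic and indel records are
    skipped and counted.  Every genotype must be phased ('|') and complete:
    an unphased or missing allele is a hard error, because the copying model
    requires known haplotypes.
    """
    chrom = None
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    columns: list[np.ndarray] = []
    skipped = {"multiallelic": 0, "indel_or_non_snp": 0}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{vcf_path}: no samples in panel VCF")
        for rec in vcf:
            if not _region_match(rec.chrom, rec.pos, region):
                continue
            if rec.alts is not None and len(rec.alts) > 1:
                skipped["multiallelic"] += 1
                continue
            if not _is_biallelic_snp(rec):
                skipped["indel_or_non_snp"] += 1
                continue
            if chrom is None:
                chrom = rec.chrom
            elif rec.chrom != chrom:
                raise ValueError(
                    f"panel spans multiple chromosomes ({chrom}, {rec.chrom}); "
                    "restrict with region="
                )
            col = np.empty(2 * len(samples), dtype=np.uint8)
            for i, name in enumerate(samples):
                call = rec.samples[name]
                alleles = call["GT"]
                if len(alleles) != 2 or any(a is None for a in alleles):
                    raise ValueError(
                        f"{vcf_path}: missing or non-diploid GT for {name} "
                        f"at {rec.chrom}:{rec.pos}"
                    )
                if not call.phased:
                    raise ValueError(
                        f"{vcf_path}: unphased genotype for {name} at "
                        f"{rec.chrom}:{rec.pos}; the panel must be fully phased"
                    )
                col[2 * i] = alleles[0]
                col[2 * i + 1] = alleles[1]
            positions.append(rec.pos)
            refs.append(rec.ref.upper())
            alts.append(rec.alts[0].upper())
            columns.append(col)
    if not columns:
        raise ValueError(f"{vcf_path}: no usable biallelic SNP records in region")
    panel = ReferencePanel(
        chrom=chrom,
        positions=np.array(positions),
        ref_alleles=np.array(refs),
        alt_alleles=np.array(alts),
        haplotypes=np.column_stack(columns),
        sample_names=samples,
        skipped=skipped,
    )
    logger.info(
        "panel: H=%d haplotypes, M=%d sites, skipped=%s",
        panel.n_haplotypes,
        panel.n_sites,
        skipped,
    )
    return panel


def _sample_field(call, key):
    try:
        value = call[key]
    except KeyError:
        return None
    if value is None:
        return None
    if any(v is None for v in value):
        return None
    return value


def read_target_likelihoods(vcf_path, sample_id: str, panel: ReferencePanel) -> LikelihoodMatrix:
    """Load genotype likelihoods for one sample, aligned to the panel.

    GL (log10) is converted via 10**GL, PL (phred) via 10**(-PL/10); each
    row is then rescaled so its maximum entry is 1.  Panel sites with no
    matching target record — and matched records with a missing GL/PL value
    — get the uniform triplet with observed=False.  Target records that do
    not match any panel site (including swapped ref/alt) are dropped and
    counted.
    """
    key_to_row = {
        (int(p), r, a): i
        for i, (p, r, a) in enumerate(
            zip(panel.positions, panel.ref_alleles, panel.alt_alleles)
        )
    }
    lik = np.full((panel.n_sites, 3), 1.0)
    observed = np.zeros(panel.n_sites, dtype=bool)
    n_unmatched = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        if sample_id not in vcf.header.samples:
            raise KeyError(f"sample {sample_id!r} not present in {vcf_path}")
        has_gl = "GL" in vcf.header.formats
        has_pl = "PL" in vcf.header.formats
        if not (has_gl or has_pl):
            raise ValueError(
                f"{vcf_path}: FORMAT defines neither GL nor PL; "
                "genotype-likelihood input is required"
            )
        for rec in vcf:
            if not _is_biallelic_snp(rec):
                n_unmatched += 1
                continue
            if rec.chrom != panel.chrom:
                n_unmatched += 1
                continue
            row = key_to_row.get((rec.pos, rec.ref.upper(), rec.alts[0].upper()))
            if row is None:
                n_unmatched += 1
                continue
            call = rec.samples[sample_id]
            triplet = None
            gl = _sample_field(call, "GL") if has_gl else None
            if gl is not None and len(gl) == 3:
                triplet = np.power(10.0, np.asarray(gl, dtype=float))
            else:
                pl = _sample_field(call, "PL") if has_pl else None
                if pl is not None and len(pl) == 3:
                    triplet = np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)
            if triplet is None or triplet.max() <= 0:
                continue  # missing data at a matched record: stays uniform
            lik[row] = triplet / triplet.max()
            observed[row] = True
    if n_unmatched:
        logger.info(
            "target %s: %d records did not match the panel and were dropped",
            sample_id,
            n_unmatched,
        )
    return LikelihoodMatrix(lik, observed, n_unmatched_target_records=n_unmatched)


def read_truth_genotypes(vcf_path, sample_id: str, panel: ReferencePanel) -> np.ndarray:
    """Genotypes (alt-allele counts) for one sample, aligned to the panel.

    Returns an (M,) int8 array; panel sites absent from the truth VCF, or
    with a missing call, are coded -1.
    """
    key_to_row = {
        (int(p), r, a): i
        for i, (p, r, a) in enumerate(
            zip(panel.positions, panel.ref_alleles, panel.alt_alleles)
        )
    }
    out = np.full(panel.n_sites, -1, dtype=np.int8)
    with pysam.VariantFile(str(vcf_path)) as vcf:
        if sample_id not in vcf.header.samples:
            raise KeyError(f"sample {sample_id!r} not present in {vcf_path}")
        for rec in vcf:
            if not _is_biallelic_snp(rec) or rec.chrom != panel.chrom:
                continue
            row = key_to_row.get((rec.pos, rec.ref.upper(), rec.alts[0].upper()))
            if row is None:
                continue
            alleles = rec.samples[sample_id]["GT"]
            if alleles is None or any(a is None for a in alleles):
                continue
            out[row] = sum(alleles)
    return out


def read_genetic_map(path) -> GeneticMap:
    """Parse a plain-text genetic map.

    Two dialects, autodetected by column count: 3 columns = HapMap style
    (position, rate cM/Mb, cumulative cM — the cumulative column is used);
    4 columns = PLINK style (chrom, id, cM, position).  A header line is
    detected and skipped automatically.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty genetic map")
    first = df.iloc[0]
    try:
        float(first.iloc[-1])
        float(first.iloc[-2])
    except ValueError:
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"{path}: genetic map has a header but no data rows")
    if df.shape[1] == 3:
        pos = df.iloc[:, 0].astype(float).astype(np.int64)
        cm = df.iloc[:, 2].astype(float)
    elif df.shape[1] == 4:
        pos = df.iloc[:, 3].astype(float).astype(np.int64)
        cm = df.iloc[:, 2].astype(float)
    else:
        raise ValueError(
            f"{path}: expected 3 (HapMap) or 4 (PLINK) columns, got {df.shape[1]}"
        )
    order = np.argsort(pos.to_numpy())
    return GeneticMap(pos.to_numpy()[order], cm.to_numpy()[order])


def write_genetic_map(path, positions, cumulative_cm) -> None:
    """Write a 3-column HapMap-style map (position, rate cM/Mb, cumulative cM)."""
    positions = np.asarray(positions)
    cm = np.asarray(cumulative_cm, dtype=float)
    rates = np.zeros_like(cm)
    if len(positions) > 1:
        rates[:-1] = np.diff(cm) / np.maximum(np.diff(positions), 1) * 1e6
        rates[-1] = rates[-2] if len(rates) > 1 else 0.0
    with open(path, "w") as fh:
        fh.write("position\trate(cM/Mb)\tcM\n")
        for p, r, c in zip(positions, rates, cm):
            fh.write(f"{int(p)}\t{r:.8f}\t{c:.8f}\n")


def _base_header(chrom: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom}>")
    header.add_line("##source=lsimpute")
    return header


def round_genotype_posteriors(gp: np.ndarray, decimals: int = 3) -> np.ndarray:
    """Round GP rows to ``decimals`` places with rows summing exactly to 1.

    Largest-remainder rounding: floor every entry, then hand the leftover
    units to the entries with the largest remainders.  Each written value is
    the floor or the ceiling of the true one, so it deviates by strictly
    less than one unit in the last place (1e-3 at the default precision).
    """
    scale = 10**decimals
    scaled = np.asarray(gp, dtype=float) * scale
    base = np.floor(scaled)
    remainder = scaled - base
    deficit = np.rint(scale - base.sum(axis=1)).astype(int)
    order = np.argsort(-remainder, axis=1, kind="stable")
    for i, d in enumerate(deficit):
        base[i, order[i, :d]] += 1
    return base / scale


def write_imputed_vcf(result, panel: ReferencePanel, sample_id: str, out_path) -> None:
    """Write imputation output: phased GT, GP (3 decimals, rows sum to 1), DS.

    GT comes from the max-posterior state's implied alleles; DS is the
    dosage GP(1) + 2*GP(2) computed from the written (rounded) GP.
    """
    if result.gp.shape[0] != panel.n_sites:
        raise ValueError("result does not cover all panel sites")
    header = _base_header(panel.chrom)
    header.formats.add("GT", 1, "String", "Imputed phased genotype")
    header.formats.add("GP", "G", "Float", "Posterior genotype probabilities")
    header.formats.add("DS", "A", "Float", "Estimated alternative allele dosage")
    header.add_sample(sample_id)
    gp = round_genotype_posteriors(result.gp)
    ds = gp[:, 1] + 2.0 * gp[:, 2]
    with pysam.VariantFile(str(out_path), "w", header=header) as out:
        for j in range(panel.n_sites):
            rec = out.new_record(
                contig=panel.chrom,
                start=int(panel.positions[j]) - 1,
                alleles=(str(panel.ref_alleles[j]), str(panel.alt_alleles[j])),
            )
            call = rec.samples[sample_id]
            call["GT"] = (int(result.haplotypes[0, j]), int(result.haplotypes[1, j]))
            call.phased = True
            call["GP"] = tuple(float(x) for x in gp[j])
            call["DS"] = float(ds[j])
            out.write(rec)


def write_panel_vcf(panel: ReferencePanel, out_path, sample_names=None) -> None:
    """Write a panel as a phased diploid VCF (haplotypes 2i, 2i+1 per sample)."""
    H = panel.n_haplotypes
    if H % 2 != 0:
        raise ValueError("panel VCF output needs an even number of haplotypes")
    n = H // 2
    if sample_names is None:
        sample_names = panel.sample_names or [f"REF{i:03d}" for i in range(n)]
    if len(sample_names) != n:
        raise ValueError("need one sample name per haplotype pair")
    header = _base_header(panel.chrom)
    header.formats.add("GT", 1, "String", "Phased genotype")
    for name in sample_names:
        header.add_sample(name)
    with pysam.VariantFile(str(out_path), "w", header=header) as out:
        for j in range(panel.n_sites):
            rec = out.new_record(
                contig=panel.chrom,
                start=int(panel.positions[j]) - 1,
                alleles=(str(panel.ref_alleles[j]), str(panel.alt_alleles[j])),
            )
            for i, name in enumerate(sample_names):
                call = rec.samples[name]
                call["GT"] = (
                    int(panel.haplotypes[2 * i, j]),
                    int(panel.haplotypes[2 * i + 1, j]),
                )
                call.phased = True
            out.write(rec)


def write_truth_vcf(panel_like, genotypes: np.ndarray, sample_names, out_path) -> None:
    """Write truth genotypes (rows of ``genotypes``: one sample each) as unphased GT."""
    genotypes = np.atleast_2d(np.asarray(genotypes))
    header = _base_header(panel_like.chrom)
    header.formats.add("GT", 1, "String", "True genotype")
    for name in sample_names:
        header.add_sample(name)
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}
    with pysam.VariantFile(str(out_path), "w", header=header) as out:
        for j in range(genotypes.shape[1]):
            rec = out.new_record(
                contig=panel_like.chrom,
                start=int(panel_like.positions[j]) - 1,
                alleles=(str(panel_like.ref_alleles[j]), str(panel_like.alt_alleles[j])),
            )
            for i, name in enumerate(sample_names):
                rec.samples[name]["GT"] = gt_codes[int(genotypes[i, j])]
            out.write(rec)


def write_gl_vcf(
    likelihoods: LikelihoodMatrix, panel_like, sample_id: str, out_path
) -> None:
    """Write simulated genotype likelihoods as a standard log10-scaled GL field.

    Unobserved sites carry the uniform triplet (equal GL values); zero
    likelihoods are floored at 1e-300 before taking log10 so the field stays
    finite.
    """
    header = _base_header(panel_like.chrom)
    header.formats.add("GT", 1, "String", "Genotype (uncalled)")
    header.formats.add("GL", "G", "Float", "Log10-scaled genotype likelihoods")
    header.add_sample(sample_id)
    with pysam.VariantFile(str(out_path), "w", header=header) as out:
        for j in range(likelihoods.n_sites):
            rec = out.new_record(
                contig=panel_like.chrom,
                start=int(panel_like.positions[j]) - 1,
                alleles=(str(panel_like.ref_alleles[j]), str(panel_like.alt_alleles[j])),
            )
            # a missing diploid GT sets the ploidy the Number=G field needs
            rec.samples[sample_id]["GT"] = (None, None)
            row = np.maximum(likelihoods.likelihoods[j], 1e-300)
            rec.samples[sample_id]["GL"] = tuple(float(x) for x in np.log10(row))
            out.write(rec)
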