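"""File input and per-variant analysis tables.

Genotypes come either from a VCF (GT field, biallelic records; multiallelic
records are skipped with a warning) or from a TSV matrix with one row per
variant and one 0/1/2 column per sample.  Phenotypes and covariates are
TSVs keyed by sample id.  Samples are matched by intersecting ids; the
minor allele is always the one counted, so genotype 2 means two copies of
the less frequent allele regardless of how REF/ALT were assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import residualize, z_test
from .effects import EstimationError, GroupedSample, estimate_f
from .intervals import interval
from .max3 import max3_test

logger = logging.getLogger("npodds")

__all__ = ["VariantRecord", "read_inputs", "analyze_variants",
           "read_genotypes", "read_phenotype", "write_genotype_tsv"]

MISSING = -1  # in-memory code for a missing genotype


@dataclass
class VariantRecord:
    """One biallelic variant: id, optional coordinates, per-sample 0/1/2."""

    id: str
    genotypes: np.ndarray
    chrom: str | None = None
    pos: int | None = None  # 1-based, as in VCF
    n_missing: int = 0
    recoded: bool = False  # True when ALT was the major allele and counts were flipped


def _recode_minor(gt: np.ndarray) -> tuple[np.ndarray, bool]:
    """Flip counts if the counted (ALT) allele is the major one."""
    obs = gt[gt != MISSING]
    if obs.size and obs.mean() > 1.0:  # ALT frequency > 0.5
        flipped = np.where(gt == MISSING, MISSING, 2 - gt)
        return flipped.astype(np.int8), True
    return gt.astype(np.int8), False


def _read_vcf(path: str) -> tuple[list[VariantRecord], list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants = []
    for v in vcf:
        if len(v.ALT) != 1:
            logger.warning("skipping multiallelic record %s:%s", v.CHROM, v.POS)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        types = np.asarray(v.gt_types)
        gt = np.select([types == 0, types == 1, types == 3], [0, 1, 2], MISSING)
        gt, recoded = _recode_minor(gt.astype(np.int8))
        vid = v.ID or f"{v.CHROM}:{v.POS}"
        variants.append(VariantRecord(
            id=vid, genotypes=gt, chrom=v.CHROM, pos=v.POS,
            n_missing=int((gt == MISSING).sum()), recoded=recoded,
        ))
    return variants, samples


def _read_genotype_tsv(path: str) -> tuple[list[VariantRecord], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    samples = list(df.columns[1:])
    variants = []
    for _, row in df.iterrows():
        vals = row.iloc[1:]
        gt = pd.to_numeric(vals, errors="coerce").to_numpy()
        gt = np.where(np.isnan(gt), MISSING, gt)
        if not np.isin(gt, (MISSING, 0, 1, 2)).all():
            raise ValueError(f"variant {row[id_col]!r}: genotypes must be 0/1/2 or missing")
        gt, recoded = _recode_minor(gt.astype(np.int8))
        variants.append(VariantRecord(
            id=str(row[id_col]), genotypes=gt,
            n_missing=int((gt == MISSING).sum()), recoded=recoded,
        ))
    return variants, samples


def read_genotypes(path) -> tuple[list[VariantRecord], list[str]]:
    """Dispatch on extension: .vcf[.gz] via cyvcf2, otherwise TSV matrix."""
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_vcf(p)
    return _read_genotype_tsv(p)


def read_phenotype(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("phenotype file needs columns: sample_id, value")
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if vals.isna().any():
        bad = int(np.argmax(vals.isna().to_numpy())) + 2  # 1-based incl. header
        raise ValueError(f"non-numeric phenotype value at line {bad} of {path}")
    return pd.Series(vals.to_numpy(), index=df.iloc[:, 0].astype(str), name="phenotype")


def read_inputs(genotype_path, phenotype_path, covariate_path=None):
    """Load and sample-match genotypes, phenotype and optional covariates."""
    variants, gsamples = read_genotypes(genotype_path)
    pheno = read_phenotype(phenotype_path)
    common = [s for s in gsamples if s in set(pheno.index)]
    if not common:
        raise ValueError("no overlapping samples between genotype and phenotype files")
    dropped = (len(gsamples) - len(common)) + (pheno.index.size - len(common))
    if dropped:
        logger.warning("%d samples outside the genotype/phenotype intersection dropped",
                       dropped)
    idx = [gsamples.index(s) for s in common]
    for v in variants:
        v.genotypes = v.genotypes[idx]
        v.n_missing = int((v.genotypes == MISSING).sum())
    pheno = pheno.loc[common]
    covariates = None
    if covariate_path is not None:
        cov = pd.read_csv(covariate_path, sep="\t", dtype={0: str})
        cov = cov.set_index(cov.columns[0])
        missing = [s for s in common if s not in cov.index]
        if missing:
            raise ValueError(f"covariate file is missing samples: {missing[:5]}")
        covariates = cov.loc[common].apply(pd.to_numeric)
    return variants, pheno, covariates


def analyze_variants(variants, phenotype, covariates=None, ci_method="wilson",
                     alpha=0.05, model="all", bonferroni=True) -> pd.DataFrame:
    """Per-variant nonparametric odds analysis table.

    Missing genotypes are dropped per variant (complete-case); variants whose
    genotype groups are degenerate yield NA cells with a reason code instead
    of aborting the run.
    """
    pheno = np.asarray(phenotype, dtype=float)
    outcome_full = residualize(pheno, covariates) if covariates is not None else pheno
    rows = []
    for v in variants:
        gt = np.asarray(v.genotypes)
        keep = gt != MISSING
        row = {"variant": v.id, "chrom": v.chrom, "pos": v.pos,
               "n_missing": int((~keep).sum()), "reason": ""}
        y, g = outcome_full[keep], gt[keep]
        sample = GroupedSample.from_genotypes(y, g)
        row.update(n0=sample.n0, n1=sample.n1, n2=sample.n2)
        if len(np.unique(g)) < 2:
            row["reason"] = "monomorphic"
            rows.append(row)
            continue
        try:
            if sample.n0 and sample.n1:
                e1 = estimate_f(sample.y0, sample.y1, label="f1")
                row.update(f1=e1.f_hat, lambda1=e1.lambda_hat)
                if e1.var_f > 0 and np.isfinite(e1.var_f):
                    ci = interval(e1, alpha, method=ci_method)
                    row.update(lambda1_low=ci.lower, lambda1_high=ci.upper)
            if sample.n0 and sample.n2:
                e2 = estimate_f(sample.y0, sample.y2, label="f2")
                row.update(f2=e2.f_hat, lambda2=e2.lambda_hat)
                if e2.var_f > 0 and np.isfinite(e2.var_f):
                    ci = interval(e2, alpha, method=ci_method)
                    row.update(lambda2_low=ci.lower, lambda2_high=ci.upper)
            wanted = (("recessive", "additive", "dominant") if model in ("all", "max3")
                      else (model,))
            for m in wanted:
                try:
                    t = z_test(sample, m)
                    row[f"p_{m[0].upper()}"] = t.p_value
                    row[f"Z_{m[0].upper()}"] = t.statistic
                except EstimationError:
                    pass
            if model in ("all", "max3"):
                try:
                    t = max3_test(sample)
                    row.update(max3=t.statistic, p_max3=t.p_value)
                except EstimationError:
                    pass
        except EstimationError as exc:
            row["reason"] = str(exc)
        rows.append(row)
    out = pd.DataFrame(rows)
    if bonferroni:
        pcol = ("p_max3" if "p_max3" in out.columns
                else f"p_{model[0].upper()}" if f"p_{model[0].upper()}" in out.columns
                else None)
        if pcol:
            m = out[pcol].notna().sum()
            out["p_bonferroni"] = np.minimum(out[pcol] * m, 1.0)
    return out


def write_genotype_tsv(variants, samples, path) -> None:
    """Write the TSV genotype dialect (round-trips with read_genotypes)."""
    data = {"variant": [v.id for v in variants]}
    mat = np.vstack([v.genotypes for v in variants]) if variants else np.empty((0, len(samples)))
    df = pd.DataFrame(mat, columns=samples, dtype=object)
    df = df.replace(MISSING, np.nan)
    out = pd.concat([pd.DataFrame(data), df], axis=1)
    out.to_csv(path, sep="\t", index=False)
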