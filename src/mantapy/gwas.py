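"""Multivariate GWAS: VCF + phenotype/covariate TSVs -> association table.

Per variant, the pipeline applies the standard pre-test filters (biallelic,
MAF, missingness, minimum individuals per genotype group), drops samples
with a missing call, fits covariates + genotype with Type I sums of squares
(genotype last) and reports the asymptotic p-value of the genotype term.
Variants failing a filter are emitted to a skip log with a single primary
reason.

Also provides the genotype x condition interaction test used for
condition-biased QTL mapping (e.g. population-biased splicing QTLs), with
the maximum-difference (MD) interpretability summary: per condition, the
largest absolute difference in covariate-adjusted mean trait value between
genotype groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import orth_basis
from .model import AssociationResult, MantaModel

__all__ = ["GwasConfig", "gwas_run", "load_table", "interaction_test"]


@dataclass
class GwasConfig:
    maf_min: float = 0.01
    missing_max: float = 0.05
    min_per_genotype_group: int = 10
    n_pcs: int = 0
    covariates: list[str] = field(default_factory=list)
    genotype_coding: str = "additive"  # or "categorical"
    interaction: str | None = None  # condition column for GxE testing
    alpha_gw: float = 5e-8

    def __post_init__(self):
        if not 0 <= self.maf_min <= 1 or not 0 <= self.missing_max <= 1:
            raise ValueError("filter thresholds must lie in [0, 1]")


def load_table(path, id_column: str = "id") -> pd.DataFrame:
    """Read a TSV with a sample-id column; returns a frame indexed by id."""
    df = pd.read_csv(path, sep="\t", dtype={id_column: str})
    if id_column not in df.columns:
        raise ValueError(f"column {id_column!r} missing from {path}")
    return df.set_index(id_column)


def _doses_from_variant(variant, n_samples: int) -> np.ndarray:
    """Alternate-allele dose per sample from the GT field; -1 = missing."""
    gts = np.asarray(variant.genotypes, dtype=int)[:, :2]
    dose = np.where((gts < 0).any(axis=1), -1, gts.clip(min=0).sum(axis=1))
    return dose.astype(np.int16)


def _variant_filter(dose: np.ndarray, config: GwasConfig) -> str | None:
    """First failing filter's reason, or None if the variant passes."""
    n = dose.size
    called = dose >= 0
    if called.sum() == 0:
        return "all_missing"
    if (n - called.sum()) / n >= config.missing_max:
        return "missingness"
    d = dose[called]
    af = d.mean() / 2.0
    maf = min(af, 1.0 - af)
    if maf < config.maf_min:
        return "maf"
    counts = np.bincount(d, minlength=3)
    observed = counts[counts > 0]
    if observed.size < 2 or observed.min() < config.min_per_genotype_group:
        return "group_count"
    return None


def gwas_run(
    vcf_path,
    pheno_tsv,
    covar_tsv=None,
    config: GwasConfig | None = None,
    log=None,
):
    """Run the per-variant multivariate association scan.

    Returns ``(results, skipped)``: a per-variant association DataFrame
    (chrom, pos, id, ref, alt, n, maf, df, pseudo_F, p, flags) and a skip
    log DataFrame (variant id, reason).  Sample IDs are reconciled across
    the VCF header and the TSV id columns; zero overlap is fatal.
    """
    from cyvcf2 import VCF

    config = config or GwasConfig()
    pheno = load_table(pheno_tsv)
    covar = load_table(covar_tsv) if covar_tsv is not None else None
    if pheno.isna().any().any():
        raise ValueError("phenotype table contains missing values")

    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    common = [s for s in vcf_samples if s in pheno.index]
    if covar is not None:
        common = [s for s in common if s in covar.index]
    if not common:
        raise ValueError("no overlapping samples between VCF and phenotype table")
    sample_rows = np.array([vcf_samples.index(s) for s in common])
    Y_all = pheno.loc[common].to_numpy(dtype=float)
    cov_frame = covar.loc[common].copy() if covar is not None else pd.DataFrame(index=common)
    covar_cols = config.covariates or list(cov_frame.columns)

    rows, skipped = [], []
    interaction = config.interaction
    for i, variant in enumerate(vcf):
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            skipped.append((vid, "not_biallelic"))
            continue
        try:
            dose = _doses_from_variant(variant, len(vcf_samples))[sample_rows]
        except Exception:
            skipped.append((vid, "malformed_record"))
            continue
        reason = _variant_filter(dose, config)
        if reason is not None:
            skipped.append((vid, reason))
            continue
        called = dose >= 0
        Y = Y_all[called]
        d = dose[called].astype(float)
        data = cov_frame.loc[np.asarray(common)[called]].reset_index(drop=True)
        maf = min(d.mean() / 2.0, 1.0 - d.mean() / 2.0)
        if interaction is not None:
            res = interaction_test(
                Y,
                d.astype(int),
                data[interaction],
                data[[c for c in covar_cols if c != interaction]],
                min_per_group=config.min_per_genotype_group,
            )
            assoc, md = res
        else:
            data = data[covar_cols].copy()
            if config.genotype_coding == "categorical":
                data["genotype"] = pd.Categorical(dose[called].astype(int).astype(str))
            else:
                data["genotype"] = d
            formula = " + ".join(covar_cols + ["genotype"])
            assoc = (
                MantaModel(Y, data, formula, subset=["genotype"], ss_type="I")
                .fit()["genotype"]
            )
            md = {}
        row = {
            "chrom": variant.CHROM,
            "pos": variant.POS,
            "id": vid,
            "ref": variant.REF,
            "alt": variant.ALT[0],
            "n": int(called.sum()),
            "maf": maf,
            "df": assoc.df,
            "pseudo_F": assoc.pseudo_F,
            "p": assoc.p_asymptotic,
            "flags": ",".join(sorted(assoc.flags)),
        }
        row.update({f"MD_{k}": v for k, v in md.items()})
        rows.append(row)
        if log is not None and (i + 1) % 10_000 == 0:
            print(f"processed {i + 1} variants", file=log)
    results = pd.DataFrame(rows)
    skip_log = pd.DataFrame(skipped, columns=["id", "reason"])
    return results, skip_log


def _residualize(Y: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    """Residuals of Y on an intercept plus the covariate columns."""
    n = Y.shape[0]
    if covariates is None or covariates.shape[1] == 0:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    Q = orth_basis(X)
    return Y - Q @ (Q.T @ Y)


def interaction_test(
    Y: np.ndarray,
    genotype: np.ndarray,
    condition,
    covariates: pd.DataFrame | None = None,
    min_per_group: int = 10,
) -> tuple[AssociationResult, dict]:
    """Genotype x condition interaction test with the MD summary.

    Covariates are regressed out of the responses first; the model
    condition + genotype + genotype:condition (both categorical, Type I) is
    then fitted and the interaction term tested.  Every observed genotype x
    condition cell must hold at least ``min_per_group`` individuals.

    MD: per condition level, the maximum over genotype-group pairs and
    traits of the absolute difference in mean covariate-adjusted response.
    """
    Y = np.asarray(Y, dtype=float)
    geno = pd.Series(np.asarray(genotype).astype(int).astype(str), name="genotype")
    cond = pd.Series(np.asarray(condition).astype(str), name="condition")
    cells = pd.crosstab(geno, cond)
    observed = cells.to_numpy()[cells.to_numpy() > 0]
    if observed.size and observed.min() < min_per_group:
        raise ValueError(
            f"interaction cell with fewer than {min_per_group} individuals"
        )
    if (cells > 0).sum().sum() < 2:
        raise ValueError("empty interaction design")
    Yadj = _residualize(Y, covariates)
    data = pd.DataFrame({"genotype": geno, "condition": cond})
    res = MantaModel(
        Yadj,
        data,
        "condition + genotype + genotype:condition",
        subset=["genotype:condition"],
        ss_type="I",
    ).fit()["genotype:condition"]

    md = {}
    for lev in sorted(cond.unique()):
        rows = cond.to_numpy() == lev
        groups = sorted(geno[rows].unique())
        best = 0.0
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ma = Yadj[rows & (geno == groups[a]).to_numpy()].mean(axis=0)
                mb = Yadj[rows & (geno == groups[b]).to_numpy()].mean(axis=0)
                best = max(best, float(np.max(np.abs(ma - mb))))
        md[lev] = best
    return res, md
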