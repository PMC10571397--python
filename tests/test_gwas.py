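"""GWAS front end: filters, planted-causal recovery, interaction test, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from mantapy.cli import manta_test_cli, mvgwas_cli
from mantapy.evaluate import genotype_pcs, lambda_X
from mantapy.gwas import GwasConfig, gwas_run, interaction_test
from mantapy.synthetic import (
    SimScenario,
    add_missing,
    sim_binomial_snps,
    sim_phenotypes,
    sim_two_factor,
    write_traits_tsv,
    write_vcf,
)


@pytest.fixture(scope="module")
def gwas_files(tmp_path_factory):
    """Synthetic cohort with one planted causal variant (h2_v = 0.01)."""
    td = tmp_path_factory.mktemp("gwas")
    rng = np.random.default_rng(42)
    n, m, causal = 1000, 60, 7
    G = sim_binomial_snps(n, m, (0.1, 0.4), rng)
    scen = SimScenario(n=n, q=5, h2_v=0.01, beta_pattern="equal", n_traits_affected=1)
    Y, truth = sim_phenotypes(scen, x=G.values[:, causal].astype(float), rng=rng)
    vcf, ph, cv = td / "g.vcf", td / "y.tsv", td / "c.tsv"
    write_vcf(add_missing(G, 0.005, rng), vcf)
    write_traits_tsv(Y, G.sample_ids, ph)
    write_traits_tsv(rng.standard_normal((n, 2)), G.sample_ids, cv, prefix="cov")
    return {"vcf": vcf, "pheno": ph, "covar": cv, "causal_id": f"v{causal + 1}",
            "n": n, "dir": td}


class TestGwasRun:
    def test_planted_variant_has_minimum_p(self, gwas_files):
        res, _ = gwas_run(gwas_files["vcf"], gwas_files["pheno"],
                          gwas_files["covar"], GwasConfig())
        assert res.loc[res["p"].idxmin(), "id"] == gwas_files["causal_id"]
        assert set(res.columns) >= {
            "chrom", "pos", "id", "ref", "alt", "n", "maf", "df",
            "pseudo_F", "p", "flags",
        }

    def test_permuted_phenotypes_not_inflated(self, gwas_files, tmp_path):
        rng = np.random.default_rng(0)
        pheno = pd.read_csv(gwas_files["pheno"], sep="\t")
        shuffled = pheno.copy()
        shuffled.iloc[:, 1:] = pheno.iloc[rng.permutation(len(pheno)), 1:].to_numpy()
        path = tmp_path / "yperm.tsv"
        shuffled.to_csv(path, sep="\t", index=False)
        res, _ = gwas_run(gwas_files["vcf"], path, None, GwasConfig())
        assert 0.5 < lambda_X(res["p"]) < 2.0  # few variants: coarse bounds

    def test_group_count_filter(self, tmp_path):
        # variant with 9 heterozygotes fails the >= 10 per-group rule
        rng = np.random.default_rng(1)
        n = 200
        doses = np.zeros((n, 1), dtype=np.int8)
        doses[:9, 0] = 1
        from mantapy.synthetic import GenotypeMatrix

        G = GenotypeMatrix(doses, np.array([0.02]))
        write_vcf(G, tmp_path / "g.vcf")
        write_traits_tsv(rng.standard_normal((n, 2)), G.sample_ids, tmp_path / "y.tsv")
        res, skip = gwas_run(tmp_path / "g.vcf", tmp_path / "y.tsv", None,
                             GwasConfig(maf_min=0.0))
        assert len(res) == 0
        assert skip.iloc[0]["reason"] == "group_count"

    def test_multiallelic_and_maf_filters(self, tmp_path):
        rng = np.random.default_rng(2)
        n = 300
        G = sim_binomial_snps(n, 2, 0.3, rng)
        write_vcf(G, tmp_path / "g.vcf")
        # append a multiallelic record and a rare variant
        with open(tmp_path / "g.vcf", "a") as fh:
            rare = ["0/0"] * n
            rare[0] = "0/1"
            fh.write("1\t99000\tvM\tA\tG,T\t.\tPASS\t.\tGT\t"
                     + "\t".join(["0/0"] * n) + "\n")
            fh.write("1\t99100\tvR\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(rare) + "\n")
        write_traits_tsv(rng.standard_normal((n, 2)), G.sample_ids, tmp_path / "y.tsv")
        res, skip = gwas_run(tmp_path / "g.vcf", tmp_path / "y.tsv", None, GwasConfig())
        reasons = dict(zip(skip["id"], skip["reason"]))
        assert reasons["vM"] == "not_biallelic"
        assert reasons["vR"] == "maf"

    def test_no_overlapping_samples_fatal(self, gwas_files, tmp_path):
        bad = pd.read_csv(gwas_files["pheno"], sep="\t")
        bad["id"] = ["Z" + str(i) for i in range(len(bad))]
        path = tmp_path / "bad.tsv"
        bad.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="overlapping"):
            gwas_run(gwas_files["vcf"], path, None, GwasConfig())


class TestGenotypePCs:
    def test_scores_orthogonal(self, rng):
        G = sim_binomial_snps(100, 500, 0.3, rng)
        pcs = genotype_pcs(G, 4)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.diag(gram).max()

    def test_k_zero_gives_empty_block(self, rng):
        G = sim_binomial_snps(20, 50, 0.3, rng)
        assert genotype_pcs(G, 0).shape == (20, 0)


class TestInteraction:
    def test_condition_specific_effect_detected(self):
        rng = np.random.default_rng(5)
        n = 600
        cond = np.where(np.arange(n) % 2 == 0, "EA", "AA")
        x = rng.binomial(2, 0.3, n)
        Y = rng.standard_normal((n, 3))
        active = cond == "EA"
        Y[active, 0] += 0.7 * x[active]
        res, md = interaction_test(Y, x, cond, None)
        assert res.p_asymptotic < 1e-6
        # planted MD in EA is 0.7 * 2 = 1.4; AA differences are noise only
        assert md["EA"] > 1.0
        assert md["AA"] < 0.6

    def test_shared_effect_gives_uniform_interaction_p(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(6)
        ps = []
        for _ in range(150):
            n = 240
            cond = np.where(np.arange(n) % 2 == 0, "EA", "AA")
            x = rng.binomial(2, 0.4, n)
            Y = rng.standard_normal((n, 2)) + 0.5 * x[:, None]
            res, _ = interaction_test(Y, x, cond, None, min_per_group=3)
            ps.append(res.p_asymptotic)
        assert kstest(ps, "uniform").pvalue > 1e-3

    def test_power_decreases_with_group_imbalance(self):
        # fixed n, growing imbalance between conditions -> fewer detections
        rng = np.random.default_rng(7)
        n = 400
        rates = []
        for frac_minor in (0.5, 0.1):
            hits = 0
            reps = 60
            for _ in range(reps):
                cond = np.where(rng.random(n) < frac_minor, "AA", "EA")
                x = rng.binomial(2, 0.4, n)
                Y = rng.standard_normal((n, 2))
                active = cond == "AA"
                Y[active, 0] += 0.6 * x[active]
                try:
                    res, _ = interaction_test(Y, x, cond, None, min_per_group=5)
                except ValueError:
                    continue
                hits += res.p_asymptotic < 0.05
            rates.append(hits / reps)
        assert rates[0] > rates[1]

    def test_sparse_cell_raises(self):
        rng = np.random.default_rng(8)
        n = 60
        cond = np.array(["EA"] * 55 + ["AA"] * 5)
        x = rng.binomial(2, 0.5, n)
        Y = rng.standard_normal((n, 2))
        with pytest.raises(ValueError, match="fewer than"):
            interaction_test(Y, x, cond, None, min_per_group=10)


class TestCli:
    def test_manta_test_cli_outputs_table(self, tmp_path, rng):
        Y, design = sim_two_factor(60, 3, delta=1.0, rng=rng)
        ids = [f"S{i}" for i in range(60)]
        write_traits_tsv(Y, ids, tmp_path / "y.tsv")
        design.insert(0, "id", ids)
        design.to_csv(tmp_path / "x.tsv", sep="\t", index=False)
        runner = CliRunner()
        out = runner.invoke(
            manta_test_cli,
            ["--y", str(tmp_path / "y.tsv"), "--x", str(tmp_path / "x.tsv"),
             "--model", "A+B+A:B", "--test", "A:B", "--perm", "99"],
        )
        assert out.exit_code == 0, out.output
        header = out.output.splitlines()[0].split("\t")
        assert {"term", "df", "sum_sq", "pseudo_F", "p_asymptotic",
                "p_permutation"} <= set(header)

    def test_mvgwas_cli_end_to_end(self, gwas_files, tmp_path):
        runner = CliRunner()
        out_tsv = tmp_path / "res.tsv"
        out = runner.invoke(
            mvgwas_cli,
            ["--vcf", str(gwas_files["vcf"]), "--pheno", str(gwas_files["pheno"]),
             "--covar", str(gwas_files["covar"]), "--out", str(out_tsv),
             "--skip-log", str(tmp_path / "skip.tsv")],
        )
        assert out.exit_code == 0, out.output
        res = pd.read_csv(out_tsv, sep="\t")
        assert res.loc[res["p"].idxmin(), "id"] == gwas_files["causal_id"]
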