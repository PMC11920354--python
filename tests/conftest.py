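"""Shared builders for simulated pipelines at test scale."""

import logging

import numpy as np
import pytest

from polygbs import gbs_io, grm as grm_mod, mixed_model, synthetic_data

# the ridge warnings for the (singular by construction) centered G are
# expected; keep test output readable
logging.getLogger("polygbs.mixed_model").setLevel(logging.ERROR)
logging.getLogger("polygbs.validation").setLevel(logging.ERROR)


def single_trait_config(seed, n_mothers=100, V_M=15085.7, V_C=79075.3, V_E=482725.8,
                        **kwargs):
    """One-trait simulation at the published yield-first-cut magnitudes."""
    defaults = dict(
        n_mothers=n_mothers,
        n_markers=200,
        n_families=10,
        n_repeat_samples=0,
        n_years=4,
        trials_per_year=2,
        n_locations=2,
        progeny_per_mother=1,
        records_per_progeny=3,
        V_M=np.array([[V_M]]),
        V_C=np.array([[V_C]]),
        V_E=np.array([[V_E]]),
        trait_names=["y1"],
        seed=seed,
    )
    defaults.update(kwargs)
    return synthetic_data.SimulationConfig(**defaults)


def genotype_pipeline(config, method="naive", maf=0.02, depth=(1.0, 1000.0),
                      call_rate=0.5):
    """simulate -> merge -> filter -> impute -> GRM; returns (genos, cg, rd, grm)."""
    genos = synthetic_data.simulate_population(config)
    rd_raw, smap = synthetic_data.simulate_reads(genos, config)
    cg = gbs_io.merge_repeated_samples(gbs_io.continuous_genotypes(rd_raw), smap)
    rd = gbs_io.merge_repeated_depths(rd_raw, smap)
    cg_f, rd_f = gbs_io.filter_markers(cg, rd, maf, depth[0], depth[1], call_rate)
    cg_full = gbs_io.impute_missing(cg_f)
    grm = grm_mod.grm_from_genotypes(cg_full, rd_f, method=method,
                                     ploidy=config.ploidy)
    return genos, cg_full, rd_f, grm


def simulated_dataset(seed, method="naive", **config_kwargs):
    """Full single-trait dataset: (config, grm, TraitData, true GEBV)."""
    config = single_trait_config(seed, **config_kwargs)
    genos, _, _, grm = genotype_pipeline(config, method=method)
    data, true_gebv = synthetic_data.simulate_phenotypes(genos, grm, config)
    return config, grm, data, true_gebv


def dense_gblup_oracle(X, Zm, y, Sigma_m, R, Zc=None, Sigma_c=None):
    """Generalized-least-squares solve of the GBLUP model on dense matrices.

    Independent of the mixed-model-equation path: builds
    V = Zm Sigma_m Zm' [+ Zc Sigma_c Zc'] + R explicitly, estimates b by GLS
    and predicts the genetic effects as Sigma_m Zm' V^-1 (y - X b).
    """
    V = Zm @ Sigma_m @ Zm.T + R
    if Zc is not None:
        V = V + Zc @ Sigma_c @ Zc.T
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid_v = Vi @ (y - X @ b)
    m = Sigma_m @ Zm.T @ resid_v
    c = Sigma_c @ Zc.T @ resid_v if Zc is not None else None
    return b, m, c


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_vcf(tmp_path):
    """Hand-built VCF: 3 samples x 4 biallelic SNPs with enumerated AD values,
    plus one tri-allelic record that must be skipped."""
    # (sample, marker) -> (ref, alt) depths, enumerated by hand
    ad = {
        "m1": [(3, 1), (0, 0), (5, 0), (2, 2)],
        "m2": [(10, 10), (1, 3), (0, 4), (0, 0)],
        "m3": [(7, 0), (2, 0), (1, 1), (9, 3)],
    }
    samples = list(ad)
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1>",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for j in range(4):
        cells = [f"./.:{ad[s][j][0]},{ad[s][j][1]}" for s in samples]
        lines.append(
            f"chr1\t{100 + j}\tsnp{j}\tA\tT\t.\tPASS\t.\tGT:AD\t" + "\t".join(cells)
        )
    # tri-allelic record between the biallelic ones
    cells = ["./.:1,2,3" for _ in samples]
    lines.insert(7, "chr1\t99\ttri\tA\tT,G\t.\tPASS\t.\tGT:AD\t" + "\t".join(cells))
    path = tmp_path / "toy.vcf"
    path.write_text("\n".join(lines) + "\n")
    expected_ra = np.array([[3, 0, 5, 2], [10, 1, 0, 0], [7, 2, 1, 9]])
    expected_rb = np.array([[1, 0, 0, 2], [10, 3, 4, 0], [0, 0, 1, 3]])
    return path, samples, expected_ra, expected_rb
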