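import numpy as np
import pandas as pd
import pytest

from haplocis import ancestry, simulate
from conftest import small_sim


def _block(labels, informative=None, chrom="chr1"):
    m = len(labels)
    informative = [bool(l) for l in labels] if informative is None else informative
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(m)],
        "chrom": [chrom] * m,
        "pos": np.arange(m) * 100,
        "block_id": [1] * m,
        "informative": informative,
        "hap1_parent_call": [l or "" for l in labels],
    })


M, P = "maternal", "paternal"


@pytest.mark.parametrize("labels,expected", [
    ([None, None, None], "unclassified"),
    ([M, M, M, M], "non_recombinant"),
    ([M, M, P, P], "recombinant"),
    ([M, M, M, P], "non_recombinant"),     # discordant SNP filtered at 0.75
    ([M, P, M, P, M], "excluded_switching"),
])
def test_block_classification(labels, expected):
    call = ancestry.classify_block(1, _block(labels))
    assert call.block_class == expected


def test_block_spanning_chromosomes_is_structural_error():
    snps = _block([M, M])
    snps.loc[1, "chrom"] = "chr2"
    with pytest.raises(ancestry.BlockStructureError):
        ancestry.classify_block(1, snps)


@pytest.mark.parametrize("labels,removed", [
    ([M, M, M, P], 1),   # majority 0.75 reaches the threshold
    ([M, M], 0),
    ([M, P], 0),         # exact tie: never fabricate a majority
    ([M, M, P], 0),      # 2/3 below the 0.75 threshold
])
def test_filter_discordant(labels, removed):
    keep, n = ancestry.filter_discordant(np.array(labels, dtype=object), 0.75)
    assert n == removed
    assert keep.sum() == len(labels) - removed


def test_imputation_labels_all_snps_in_non_recombinant_block():
    labels = [M, M] + [None] * 100
    snps = _block(labels)
    call = ancestry.classify_block(1, snps)
    out = ancestry.impute_snp_ancestry(snps, call)
    assert (out.hap1_ancestry == M).all()
    assert (out.hap2_ancestry == P).all()
    assert (out.source == "imputed").sum() == 100


def test_unclassified_block_labels_nothing():
    snps = _block([None] * 20)
    call = ancestry.classify_block(1, snps)
    out = ancestry.impute_snp_ancestry(snps, call)
    assert (out.hap1_ancestry == "unknown").all()


def test_recombinant_block_keeps_only_informative_labels():
    snps = _block([M, M, None, None, P, P])
    call = ancestry.classify_block(1, snps)
    assert call.block_class == "recombinant"
    out = ancestry.impute_snp_ancestry(snps, call)
    assert list(out.hap1_ancestry) == [M, M, "unknown", "unknown", P, P]
    assert (out.loc[out.hap1_ancestry != "unknown", "source"] == "informative").all()


def test_imputation_never_contradicts_retained_informative_snp():
    snps = _block([M, M, M, P, None])
    call = ancestry.classify_block(1, snps)
    out = ancestry.impute_snp_ancestry(snps, call)
    retained = set(call.retained_snp_ids)
    for row in out.itertuples(index=False):
        if row.snp_id in retained:
            orig = snps.set_index("snp_id").hap1_parent_call[row.snp_id]
            assert row.hap1_ancestry == orig


def _sv_case(labels, positions, block_class="recombinant", hap=1):
    anc = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(len(labels))],
        "block_id": 1,
        "pos": positions,
        "hap1_ancestry": labels,
    })
    anc["hap2_ancestry"] = anc.hap1_ancestry.map(ancestry.OPPOSITE).fillna("unknown")
    blocks = pd.DataFrame({"block_id": [1], "class": [block_class],
                           "hap1_ancestry": [M if block_class == "non_recombinant" else ""]})
    sv = pd.Series({"sv_id": "sv1", "block_id": 1, "haplotype": hap,
                    "start": 5_000, "end": 5_100})
    return sv, anc, blocks


def test_sv_majority_vote_of_nearest_neighbors():
    labels = [M] * 4 + [P] + [M] * 4 + [P]      # 8 maternal of 10
    pos = list(range(1_000, 5_000, 1_000)) + [4_900] \
        + list(range(5_200, 9_200, 1_000)) + [9_900]
    sv, anc, blocks = _sv_case(labels, pos)
    assert ancestry.impute_sv_ancestry(sv, anc, blocks) == M


def test_sv_tie_gives_unknown():
    labels = [M] * 5 + [P] * 5
    pos = list(range(0, 5_000, 1_000)) + list(range(5_200, 10_200, 1_000))
    sv, anc, blocks = _sv_case(labels, pos)
    assert ancestry.impute_sv_ancestry(sv, anc, blocks) == "unknown"


def test_sv_in_non_recombinant_block_uses_block_ancestry():
    labels = [P] * 10    # neighbors all paternal, but the block says maternal
    pos = list(range(1_000, 11_000, 1_000))
    sv, anc, blocks = _sv_case(labels, pos, block_class="non_recombinant")
    assert ancestry.impute_sv_ancestry(sv, anc, blocks) == M
    sv["haplotype"] = 2
    assert ancestry.impute_sv_ancestry(sv, anc, blocks) == P


def test_sv_with_no_labeled_snps_is_unknown():
    sv, anc, blocks = _sv_case(["unknown"] * 4, [1, 2, 3, 4])
    assert ancestry.impute_sv_ancestry(sv, anc, blocks) == "unknown"


def _labels_frames(variants, truth, which):
    source = truth.snp_hap1_actual if which == "actual" else truth.snp_hap1_intended
    df = variants[["snp_id", "block_id", "pos"]].copy()
    df["hap1_ancestry"] = df.snp_id.map(source)
    df["hap2_ancestry"] = df.hap1_ancestry.map(ancestry.OPPOSITE)
    return df


def test_switch_error_estimate_zero_and_missing():
    cfg = small_sim(switch_error_rate=0.0)
    genome = simulate.simulate_genome(cfg)
    variants, _, truth = simulate.simulate_phased_variants(genome, cfg)
    obs = _labels_frames(variants, truth, "actual")
    ref = _labels_frames(variants, truth, "intended")
    est = ancestry.estimate_switch_error(obs, ref)
    assert est["hap1"] == 0.0 and est["hap2"] == 0.0
    # single-SNP blocks have no evaluable transition
    one = obs.iloc[:1]
    est1 = ancestry.estimate_switch_error(one, ref.iloc[:1])
    assert est1["hap1"] is None


def test_switch_error_estimate_recovers_configured_rate():
    cfg = small_sim(switch_error_rate=0.03, chrom_length=2_500_000,
                    snp_density=10.0, seed=21)
    genome = simulate.simulate_genome(cfg)
    variants, _, truth = simulate.simulate_phased_variants(genome, cfg)
    obs = _labels_frames(variants, truth, "actual")
    ref = _labels_frames(variants, truth, "intended")
    est = ancestry.estimate_switch_error(obs, ref)
    n = len(variants)
    half_ci = 1.96 * np.sqrt(0.03 * 0.97 / n)
    assert abs(est["hap1"] - 0.03) < 2 * half_ci
    assert est["hap1"] == est["hap2"]   # complementary labels


def test_label_complementarity_everywhere(pipeline_dir):
    out, _, _ = pipeline_dir
    anc = pd.read_csv(out / "ancestry.tsv", sep="\t")
    known = anc[anc.hap1_ancestry.isin([M, P])]
    assert (known.hap2_ancestry == known.hap1_ancestry.map(ancestry.OPPOSITE)).all()


def test_perfect_phasing_imputes_truth_exactly():
    # no switch errors, no recombinant blocks: imputed ancestry == truth
    cfg = small_sim(switch_error_rate=0.0, recombinant_fraction=0.0, seed=13)
    genome = simulate.simulate_genome(cfg)
    variants, _, truth = simulate.simulate_phased_variants(genome, cfg)
    anc, blocks = ancestry.assign_ancestry(variants)
    classified = set(blocks.loc[blocks["class"] == "non_recombinant", "block_id"])
    sub = anc[anc.block_id.isin(classified)]
    assert len(sub) > 0
    expected = sub.snp_id.map(truth.snp_hap1_actual)
    assert (sub.hap1_ancestry == expected).all()
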