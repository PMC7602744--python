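import numpy as np
import pandas as pd
import pytest

from microhost.feature_table import (
    FeatureTable,
    aggregate_to_level,
    filter_rare,
    read_feature_table,
    validate_metadata,
    write_feature_table,
    write_metadata,
)
from microhost.taxonomy import RANKS

L = {
    "g1": "Bacteria;P1;C1;O1;F1;G1",
    "g2": "Bacteria;P1;C1;O1;F1;G2",
    "g3": "Bacteria;P1;C1;O1;F2;G3",
}


def toy_table():
    counts = pd.DataFrame(
        [[10, 5, 7], [3, 0, 2]],
        index=["s1", "s2"],
        columns=[L["g1"], L["g2"], L["g3"]],
    )
    return FeatureTable(counts, level="genus")


def toy_metadata():
    return validate_metadata(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "host": ["pet", "human"],
                "species": ["cat", "human"],
                "project_id": ["p1", "p2"],
            }
        )
    )


class TestIO:
    def test_roundtrip_is_bit_identical(self, tmp_path):
        table = toy_table()
        md = toy_metadata()
        tpath, mpath = tmp_path / "t.tsv", tmp_path / "m.tsv"
        write_feature_table(table, tpath)
        write_metadata(md, mpath)
        table2, md2 = read_feature_table(tpath, mpath)
        pd.testing.assert_frame_equal(table.counts, table2.counts, check_names=False)
        write_feature_table(table2, tmp_path / "t2.tsv")
        assert tpath.read_bytes() == (tmp_path / "t2.tsv").read_bytes()

    def test_species_host_mismatch_rejected(self):
        md = pd.DataFrame(
            {"sample_id": ["a"], "host": ["human"], "species": ["cat"], "project_id": ["p"]}
        )
        with pytest.raises(ValueError, match="host inconsistent"):
            validate_metadata(md)

    def test_missing_sample_named_in_error(self, tmp_path):
        write_feature_table(toy_table(), tmp_path / "t.tsv")
        write_metadata(toy_metadata().iloc[[0]], tmp_path / "m.tsv")
        with pytest.raises(ValueError, match="s2"):
            read_feature_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    def test_duplicate_sample_ids_rejected(self):
        counts = toy_table().counts
        bad = pd.concat([counts, counts.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            FeatureTable(bad, level="genus")

    def test_non_integer_counts_rejected(self):
        counts = toy_table().counts.astype(float)
        counts.iloc[0, 0] = 1.5
        with pytest.raises(ValueError, match="integer"):
            FeatureTable(counts, level="genus")


class TestAggregation:
    def test_same_level_is_identity(self):
        table = toy_table()
        agg = aggregate_to_level(table, "genus")
        pd.testing.assert_frame_equal(agg.counts, table.counts)

    def test_family_group_sums(self):
        agg = aggregate_to_level(toy_table(), "family")
        assert agg.counts.loc["s1"].tolist() == [15, 7]  # F1 = g1+g2, F2 = g3
        assert list(agg.counts.columns) == ["Bacteria;P1;C1;O1;F1", "Bacteria;P1;C1;O1;F2"]

    @pytest.mark.parametrize("level", RANKS)
    def test_row_sums_conserved_at_every_rank(self, tiny_ds, level):
        table = tiny_ds.table
        agg = aggregate_to_level(table, level)
        assert (agg.sample_totals() == table.sample_totals()).all()

    def test_aggregation_composes_and_is_idempotent(self, tiny_ds):
        via_family = aggregate_to_level(
            aggregate_to_level(tiny_ds.table, "family"), "phylum"
        )
        direct = aggregate_to_level(tiny_ds.table, "phylum")
        pd.testing.assert_frame_equal(via_family.counts, direct.counts)
        twice = aggregate_to_level(via_family, "phylum")
        pd.testing.assert_frame_equal(twice.counts, direct.counts)

    def test_cannot_aggregate_downward(self):
        fam = aggregate_to_level(toy_table(), "family")
        with pytest.raises(ValueError):
            aggregate_to_level(fam, "genus")


def _two_class_table(rng, n_pet=10, n_human=10, n_taxa=12, zero_prob=0.6):
    counts = rng.poisson(3, size=(n_pet + n_human, n_taxa))
    counts[rng.random(counts.shape) < zero_prob] = 0
    counts[:, 0] += 1  # keep every sample non-empty
    cols = [f"Bacteria;P1;C1;O1;F1;G{i}" for i in range(n_taxa)]
    ids = [f"s{i}" for i in range(n_pet + n_human)]
    table = FeatureTable(pd.DataFrame(counts, index=ids, columns=cols), level="genus")
    md = validate_metadata(
        pd.DataFrame(
            {
                "sample_id": ids,
                "host": ["pet"] * n_pet + ["human"] * n_human,
                "species": ["dog"] * n_pet + ["human"] * n_human,
                "project_id": ["pp"] * n_pet + ["hp"] * n_human,
            }
        )
    )
    return table, md


class TestFilterRare:
    def test_boundary_examples(self):
        # taxon zero in 10/10 pets and 9/10 humans is retained (0.9 is not > 0.9);
        # zero in 10/10 of both classes is removed; a ubiquitous taxon is retained.
        counts = np.zeros((20, 3), dtype=int)
        counts[:, 0] = 1  # ubiquitous
        counts[10, 1] = 4  # one human sample positive
        cols = [f"Bacteria;P1;C1;O1;F1;G{i}" for i in range(3)]
        ids = [f"s{i}" for i in range(20)]
        table = FeatureTable(pd.DataFrame(counts, index=ids, columns=cols), level="genus")
        md = validate_metadata(
            pd.DataFrame(
                {
                    "sample_id": ids,
                    "host": ["pet"] * 10 + ["human"] * 10,
                    "species": ["cat"] * 10 + ["human"] * 10,
                    "project_id": ["pp"] * 10 + ["hp"] * 10,
                }
            )
        )
        kept = filter_rare(table, md, 0.9)
        assert list(kept.counts.columns) == cols[:2]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            table, md = _two_class_table(rng)
            t = float(rng.choice([0.3, 0.5, 0.7, 0.9]))
            kept = set(filter_rare(table, md, t).counts.columns)
            expected = set()
            for col in table.counts.columns:
                pet_zero = (table.counts.loc[md["host"] == "pet", col] == 0).mean()
                hum_zero = (table.counts.loc[md["host"] == "human", col] == 0).mean()
                if not (pet_zero > t and hum_zero > t):
                    expected.add(col)
            assert kept == expected

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        table, md = _two_class_table(rng)
        thresholds = [0.1, 0.3, 0.5, 0.7, 0.9, 1.0]
        kept = [set(filter_rare(table, md, t).counts.columns) for t in thresholds]
        for lo, hi in zip(kept, kept[1:]):
            assert lo <= hi

    def test_invalid_inputs(self, tiny_ds):
        with pytest.raises(ValueError):
            filter_rare(tiny_ds.table, tiny_ds.metadata, 1.5)
        only_pets = tiny_ds.metadata[tiny_ds.metadata["host"] == "pet"]
        sub = tiny_ds.table.subset_samples(only_pets.index)
        with pytest.raises(ValueError):
            filter_rare(sub, only_pets, 0.9)
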