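import itertools

import numpy as np
import pandas as pd
import pytest

import absearch as ab
from absearch.dbstore import (FilterConfig, apply_reduction_filters,
                              build_database, load_database, read_manifest,
                              resolve_metadata)
from absearch.errors import BuildError, LoadError, ResolutionError
from absearch.numbering import NumberedResidue, NumberedSequence
from absearch.synthetic import inject_rare_insertion


def _seq(sid, residues="EVQLV", chain="H", species="human", start=1):
    return NumberedSequence(sid, chain, species,
                            [NumberedResidue(start + i, 0, r)
                             for i, r in enumerate(residues)])


def _meta(seqs, redundancy=None):
    return pd.DataFrame({
        "sequence_id": [s.sequence_id for s in seqs],
        "species": [s.species for s in seqs],
        "chain": [s.chain_type for s in seqs],
        "disease": ["healthy"] * len(seqs),
        "v_call": ["IGHV1-58*01"] * len(seqs),
        "j_call": ["IGHJ3*02"] * len(seqs),
        "redundancy": redundancy if redundancy is not None else [1] * len(seqs),
    })


class TestBuildDatabase:
    def test_shard_arithmetic(self, tmp_path, scheme):
        seqs = [_seq(f"s{i}", "EVQLV" + "A" * i) for i in range(10)]
        man = build_database(seqs, _meta(seqs), scheme, tmp_path, shard_size=4)
        assert [sh.rows for sh in man.shards] == [4, 4, 2]
        assert man.total_unusual == 0 and man.total_encoded == 10

    def test_unusual_routed_to_sidecar(self, tmp_path, scheme):
        seqs = [_seq(f"s{i}") for i in range(10)]
        seqs[2] = inject_rare_insertion(seqs[2])
        seqs[6] = inject_rare_insertion(seqs[6])
        man = build_database(seqs, _meta(seqs), scheme, tmp_path)
        assert man.total_encoded == 8 and man.total_unusual == 2
        fasta = (tmp_path / "unusual.fasta").read_text()
        assert ">s2" in fasta and "81I" in fasta

    def test_species_partitioning(self, tmp_path, scheme):
        seqs = ([_seq(f"h{i}", species="human") for i in range(3)]
                + [_seq(f"m{i}", species="mouse") for i in range(2)])
        man = build_database(seqs, _meta(seqs), scheme, tmp_path)
        assert set(man.partitions) == {("H", "human"), ("H", "mouse")}
        rows = {(sh.chain_type, sh.species): sh.rows for sh in man.shards}
        assert rows[("H", "human")] == 3 and rows[("H", "mouse")] == 2

    def test_metadata_count_mismatch_is_build_error(self, tmp_path, scheme):
        seqs = [_seq("a"), _seq("b")]
        with pytest.raises(BuildError, match="metadata"):
            build_database(seqs, _meta(seqs).iloc[:1], scheme, tmp_path)

    def test_empty_database_round_trips(self, tmp_path, scheme):
        man = build_database([], _meta([]), scheme, tmp_path)
        db = load_database(tmp_path / "manifest.tsv")
        assert list(db.iter_shards()) == []
        assert db.manifest.total_encoded == 0


class TestReductionFilters:
    def _records(self, seqs, meta):
        return [(s, meta.iloc[i]) for i, s in enumerate(seqs)]

    def test_ambiguous_drop_counts(self):
        seqs = [_seq(f"s{i}", "EVXLV" if i < 2 else "EVQLV") for i in range(10)]
        kept, drops = apply_reduction_filters(
            self._records(seqs, _meta(seqs)), FilterConfig(drop_ambiguous=True))
        assert len(kept) == 8 and drops["ambiguous"] == 2

    def test_redundancy_threshold_from_metadata(self):
        seqs = [_seq(f"s{i}", res) for i, res in
                enumerate(["EVQLV", "DVQLV", "GVQLV"])]
        meta = _meta(seqs, redundancy=[1, 5, 7])
        kept, drops = apply_reduction_filters(
            self._records(seqs, meta), FilterConfig(min_redundancy=5))
        assert len(kept) == 2 and drops["redundancy"] == 1

    def test_redundancy_computed_when_column_absent(self):
        seqs = [_seq("a", "EVQLV"), _seq("b", "EVQLV"), _seq("c", "DVQLV")]
        meta = _meta(seqs).drop(columns=["redundancy"])
        kept, drops = apply_reduction_filters(
            self._records(seqs, meta), FilterConfig(min_redundancy=2))
        assert [s.sequence_id for s, _ in kept] == ["a", "b"]
        assert drops["redundancy"] == 1

    def test_position_one_requirement(self):
        seqs = [_seq("a"), _seq("b", start=2)]
        kept, drops = apply_reduction_filters(
            self._records(seqs, _meta(seqs)),
            FilterConfig(require_position_one=True))
        assert [s.sequence_id for s, _ in kept] == ["a"]
        assert drops["position_one"] == 1

    def test_deduplicate_keeps_first(self):
        seqs = [_seq("a", "EVQLV"), _seq("b", "EVQLV")]
        kept, drops = apply_reduction_filters(
            self._records(seqs, _meta(seqs)), FilterConfig(deduplicate=True))
        assert [s.sequence_id for s, _ in kept] == ["a"]
        assert drops["duplicate"] == 1

    @pytest.mark.parametrize("flags", list(itertools.product([False, True], repeat=4)))
    def test_conservation_under_every_filter_combination(self, tmp_path, scheme, flags):
        """encoded + unusual + filtered always equals the input count."""
        drop_amb, min_red, req_one, dedup = flags
        spec = ab.RepertoireSpec(n_sequences=40, seed=99, ambiguous_rate=0.01)
        seqs, meta = ab.generate_repertoire(spec, scheme)
        seqs[5] = inject_rare_insertion(seqs[5])
        seqs[11] = _seq("nopos1", start=2)
        seqs[12] = seqs[13]  # exact duplicate
        cfg = FilterConfig(drop_ambiguous=drop_amb,
                           min_redundancy=5 if min_red else None,
                           require_position_one=req_one, deduplicate=dedup)
        man = build_database(seqs, meta, scheme, tmp_path / "db",
                             shard_size=16, filters=cfg)
        assert (man.total_encoded + man.total_unusual + man.total_filtered
                == len(seqs) == man.total_input)


class TestLoadAndResolve:
    def test_round_trip_is_bit_exact(self, tmp_path, scheme, small_repertoire):
        seqs, meta = small_repertoire
        build_database(seqs, meta, scheme, tmp_path / "db", shard_size=100)
        db = load_database(tmp_path / "db" / "manifest.tsv")
        loaded = np.vstack([sh.matrix for sh in db.iter_shards()])
        expected = np.vstack([ab.encode(s, scheme) for s in seqs])
        # partitioning may reorder rows across (chain, species); compare as multisets
        assert loaded.shape == expected.shape
        key = lambda m: sorted(map(tuple, m.tolist()))
        assert key(loaded) == key(expected)

    def test_index_pairs_resolve_to_build_time_metadata(self, built_db, scheme,
                                                        small_repertoire):
        seqs, meta = small_repertoire
        by_id = {s.sequence_id: s for s in seqs}
        tables = built_db.metadata_tables()
        for shard in built_db.iter_shards():
            for row in range(shard.matrix.shape[0]):
                record = resolve_metadata(shard.index_pairs[row], tables)
                original = by_id[record["sequence_id"]]
                assert (shard.matrix[row] == ab.encode(original, scheme)).all()

    def test_each_encoded_sequence_in_exactly_one_partition(self, built_db):
        seen = []
        for shard in built_db.iter_shards():
            seen.extend(map(tuple, shard.index_pairs.tolist()))
        assert len(seen) == len(set(seen)) == built_db.manifest.total_encoded

    def test_missing_shard_file_is_load_error_naming_it(self, tmp_path, scheme):
        seqs = [_seq(f"s{i}") for i in range(4)]
        man = build_database(seqs, _meta(seqs), scheme, tmp_path, shard_size=2)
        victim = tmp_path / man.shards[1].matrix_file
        victim.unlink()
        db = load_database(tmp_path / "manifest.tsv")
        with pytest.raises(LoadError, match=man.shards[1].matrix_file):
            list(db.iter_shards())

    def test_corrupted_shard_fails_hash_check(self, tmp_path, scheme):
        seqs = [_seq(f"s{i}") for i in range(4)]
        man = build_database(seqs, _meta(seqs), scheme, tmp_path, shard_size=4)
        path = tmp_path / man.shards[0].matrix_file
        raw = bytearray(path.read_bytes())
        raw[0] ^= 0xFF
        path.write_bytes(bytes(raw))
        with pytest.raises(LoadError, match="hash"):
            list(load_database(tmp_path / "manifest.tsv").iter_shards())

    def test_manifest_counts_must_sum(self, tmp_path, scheme):
        seqs = [_seq(f"s{i}") for i in range(4)]
        build_database(seqs, _meta(seqs), scheme, tmp_path)
        manifest_path = tmp_path / "manifest.tsv"
        text = manifest_path.read_text().replace("total_encoded\t4",
                                                 "total_encoded\t5")
        manifest_path.write_text(text)
        with pytest.raises(LoadError, match="sum"):
            read_manifest(manifest_path)

    def test_resolve_metadata_bounds(self):
        table = pd.DataFrame({"sequence_id": ["only"]})
        assert resolve_metadata((0, 0), [table])["sequence_id"] == "only"
        with pytest.raises(ResolutionError):
            resolve_metadata((1, 0), [table])
        with pytest.raises(ResolutionError):
            resolve_metadata((0, 1), [table])
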