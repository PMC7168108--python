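from __future__ import annotations

import pytest

from cysscreen.classify import (
    CYS_RICH,
    MotifDB,
    MotifDBError,
    classify_peptide,
    cys_rich_criterion,
    load_motif_db,
    scan_motifs,
    screen_transcriptome,
    write_classified_fasta,
)
from cysscreen.config import PipelineConfig
from cysscreen.filters import PeptideCandidate, SignalPrediction
from cysscreen.motifs import MatchSpan, parse_motif
from cysscreen.orfs import NucleotideRecord
from cysscreen.synth import (
    build_precursor,
    generate_transcriptome,
    reverse_translate,
    sample_motif_realization,
)

from conftest import BUILTIN_MOTIFS


class TestLoadMotifDB:
    def test_builtin_contents(self, builtin_db):
        assert len(builtin_db.motifs) == 9
        assert {m.family for m in builtin_db.motifs} == {
            "snakins", "lipid-transfer", "hevein-like",
            "thionins", "cyclotides", "defensins",
        }
        for m in builtin_db.motifs:
            family, pattern = BUILTIN_MOTIFS[m.motif_id]
            assert m.family == family

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "db.tsv"
        p.write_text("A1\tdefensins\tCXC\nA1\tdefensins\tCC\n")
        with pytest.raises(MotifDBError, match="duplicate"):
            load_motif_db(p)

    def test_empty_db_rejected(self, tmp_path):
        p = tmp_path / "db.tsv"
        p.write_text("# only a comment\n")
        with pytest.raises(MotifDBError):
            load_motif_db(p)

    def test_parse_error_reports_line(self, tmp_path):
        p = tmp_path / "db.tsv"
        p.write_text("A1\tdefensins\tCXC\nA2\tdefensins\tCX{5,3}C\n")
        with pytest.raises(MotifDBError, match=":2"):
            load_motif_db(p)

    def test_bad_field_count(self, tmp_path):
        p = tmp_path / "db.tsv"
        p.write_text("A1 defensins CXC\n")
        with pytest.raises(MotifDBError, match=":1"):
            load_motif_db(p)


class TestCysRichCriterion:
    def test_four_cysteines(self):
        assert cys_rich_criterion("ACACACAC", 4)

    def test_none(self):
        assert not cys_rich_criterion("AAAA", 4)

    def test_boundary(self):
        assert not cys_rich_criterion("CCC", 4)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cys_rich_criterion("")


def _candidate(builtin_db, mature, cleavage=18):
    """Build a filtered candidate around a given mature sequence."""
    precursor = "M" + "KR" + "L" * 12 + "AQA" + mature
    from cysscreen.orfs import OrfCandidate

    orf = OrfCandidate("c", 1, 0, 3 * len(precursor) + 3, precursor, True)
    hits = tuple(scan_motifs(builtin_db, precursor))
    return PeptideCandidate(
        orf, SignalPrediction(True, cleavage_pos=cleavage, score=0.9),
        precursor[cleavage:], hits,
    )


class TestClassifyPeptide:
    def test_def06_only_is_defensin(self, builtin_db):
        mature = sample_motif_realization(builtin_db.get("DEF06"), seed=3)
        cls = classify_peptide(_candidate(builtin_db, mature), builtin_db)
        assert cls.family == "defensins"
        assert cls.motif_id == "DEF06"

    def test_most_specific_wins(self, builtin_db):
        # every DEF06 realization also satisfies the looser DEF32/DEF34
        mature = sample_motif_realization(builtin_db.get("DEF06"), seed=5)
        cand = _candidate(builtin_db, mature)
        hit_ids = {mid for mid, _ in cand.motif_hits}
        assert {"DEF06", "DEF32", "DEF34"} <= hit_ids
        cls = classify_peptide(cand, builtin_db)
        assert cls.motif_id == "DEF06"  # span range 0 beats the ranged motifs

    def test_cys_rich_fallback(self, builtin_db):
        cls = classify_peptide(_candidate(builtin_db, "ACACACACACAC"), builtin_db)
        assert cls.family == CYS_RICH and cls.motif_id is None

    def test_not_cys_rich_unclassified(self, builtin_db):
        cls = classify_peptide(_candidate(builtin_db, "AAAAAAAA"), builtin_db)
        assert cls.family == "unclassified"

    def test_signal_region_hits_excluded(self, builtin_db):
        mature = sample_motif_realization(builtin_db.get("CYC01"), seed=1)
        cand = _candidate(builtin_db, mature, cleavage=18)
        # pretend cleavage is downstream of all hits -> no qualifying hit
        moved = PeptideCandidate(
            cand.orf,
            SignalPrediction(True, cleavage_pos=40, score=0.9),
            cand.orf.aa_sequence[40:],
            cand.motif_hits,
        )
        cls = classify_peptide(moved, builtin_db)
        assert cls.family != "cyclotides"


class TestScreenTranscriptome:
    def test_planted_defensins_recovered(self, builtin_db):
        recs, manifest = generate_transcriptome(
            n_planted_per_family={"defensins": 6}, n_decoys=10, seed=11
        )
        res = screen_transcriptome(recs, builtin_db, PipelineConfig())
        planted_ids = {g.contig_id for g in manifest.genes}
        got = {
            c.orf.seq_id for c, cls in res.classified if cls.family == "defensins"
        }
        assert planted_ids <= got
        assert res.counts["defensins"] >= 6

    def test_empty_input(self, builtin_db):
        res = screen_transcriptome([], builtin_db)
        assert res.classified == [] and res.cys_rich == []
        assert all(v == 0 for v in res.counts.values())

    def test_stop_free_contigs_yield_nothing(self, builtin_db):
        recs = [NucleotideRecord("c1", "ATGGCA" * 40)]  # no stop codon anywhere
        res = screen_transcriptome(recs, builtin_db, PipelineConfig(require_stop=True))
        assert res.total_retained() == 0

    def test_counts_reconcile(self, builtin_db):
        recs, _ = generate_transcriptome(n_planted_per_family=2, n_decoys=20, seed=2)
        res = screen_transcriptome(recs, builtin_db)
        assert sum(res.counts.values()) == res.total_retained()

    def test_deduplication_within_contig(self, builtin_db):
        motif = builtin_db.get("CYC01")
        mature = sample_motif_realization(motif, seed=4)
        precursor = build_precursor(mature, seed=4)
        cds = reverse_translate(precursor, seed=4) + "TAA"
        contig = "TAA" + cds + "AAATAA" + cds + "AAA"
        res = screen_transcriptome(
            [NucleotideRecord("dup", contig)], builtin_db
        )
        matching = [
            c for c, cls in res.classified if c.orf.aa_sequence == precursor
        ]
        assert len(matching) == 1
        assert matching[0].orf.nt_start == 3  # lowest start kept

    def test_determinism_byte_identical(self, builtin_db, tmp_path):
        recs, _ = generate_transcriptome(n_planted_per_family=1, n_decoys=10, seed=8)
        outs = []
        for run in range(2):
            res = screen_transcriptome(recs, builtin_db, PipelineConfig(seed=8))
            p = tmp_path / f"out{run}.fasta"
            write_classified_fasta(p, res)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_adding_inert_motif_preserves_counts(self, builtin_db):
        recs, _ = generate_transcriptome(n_planted_per_family=2, n_decoys=10, seed=13)
        base = screen_transcriptome(recs, builtin_db)
        inert = parse_motif("CCCCCCCCCCCC", motif_id="INERT", family="unknown")
        extended = MotifDB(builtin_db.motifs + (inert,), builtin_db.family_order)
        ext = screen_transcriptome(recs, extended)
        for family, count in base.counts.items():
            assert ext.counts[family] >= count or family == CYS_RICH
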