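import math
import subprocess

import numpy as np
import pytest

from helpers import (
    background_equal_model,
    enum_forward_bits,
    random_model,
    single_state_model,
)
from conftest import random_protein
from ksclass.errors import (
    EmptyInputError,
    EmptyModelError,
    ParameterError,
    ProfileParseError,
    SchemaVersionError,
    UnsupportedAlphabetError,
    ValidationError,
)
from ksclass.phmm import (
    AA_INDEX,
    ProfileHMM,
    build_profile,
    forward_bitscore,
    locate_domain,
    read_hmmer3_ascii,
    read_profile_json,
    sample_sequence,
    write_profile_json,
)
from ksclass.seqio import MultipleAlignment, ProteinSequence
from ksclass.synthetic import FamilySpec, make_family_hmm


class TestForwardOracle:
    """The DP forward score must equal exhaustive path enumeration."""

    @pytest.mark.parametrize("M", [1, 2, 3])
    @pytest.mark.parametrize("model_seed", [0, 1])
    def test_matches_path_enumeration(self, M, model_seed):
        hmm = random_model(M, model_seed)
        rng = np.random.default_rng(100 * M + model_seed)
        letters = list("ACDE")  # reduced alphabet keeps enumeration small
        for L in (1, 2, 3, 4, 5):
            for _ in range(3):
                s = "".join(rng.choice(letters, size=L))
                got = forward_bitscore(hmm, ProteinSequence(id="q", residues=s))
                want = enum_forward_bits(hmm, s)
                assert got == pytest.approx(want, abs=1e-9)

    def test_x_residues_agree_with_oracle(self):
        hmm = random_model(2, 3)
        for s in ("AXA", "XX", "AXXCA"):
            got = forward_bitscore(hmm, ProteinSequence(id="q", residues=s))
            assert got == pytest.approx(enum_forward_bits(hmm, s), abs=1e-9)


class TestHandScores:
    def test_single_match_state(self):
        """M=1, 0.95 mass on 'A', forced begin->M1->end: log2(0.95/0.05)."""
        hmm = single_state_model()
        bits = forward_bitscore(hmm, ProteinSequence(id="q", residues="A"))
        assert bits == pytest.approx(math.log2(0.95 / 0.05), abs=1e-6)
        assert bits == pytest.approx(4.2479, abs=1e-4)

    def test_background_equal_model_scores_zero(self):
        """Emissions equal to background on a forced-length path: 0 bits."""
        hmm = background_equal_model(4)
        bits = forward_bitscore(hmm, ProteinSequence(id="q", residues="XXXX"))
        assert bits == pytest.approx(0.0, abs=1e-6)
        bits2 = forward_bitscore(hmm, ProteinSequence(id="q", residues="MKVA"))
        assert bits2 == pytest.approx(0.0, abs=1e-6)

    def test_empty_sequence_rejected(self):
        with pytest.raises((EmptyInputError, ParameterError)):
            forward_bitscore(single_state_model(), "")


class TestScoreProperties:
    def test_scores_finite_for_valid_inputs(self, toy_family, rng):
        for n in (5, 50, 200):
            q = random_protein(rng, n)
            assert math.isfinite(forward_bitscore(toy_family, q))
            assert math.isfinite(forward_bitscore(toy_family, q, mode="local"))

    def test_local_not_below_glocal_on_flanked_domain(self, toy_family, rng):
        core = sample_sequence(toy_family, np.random.default_rng(0)).residues
        q = ProteinSequence(
            id="q", residues=random_protein(rng, 40).residues + core + random_protein(rng, 40).residues
        )
        assert forward_bitscore(toy_family, q, mode="local") > forward_bitscore(toy_family, q)

    def test_consensus_outscores_shuffled(self):
        """Conserved-profile consensus beats its residue permutation."""
        wins = 0
        for trial in range(20):
            fam = make_family_hmm(
                FamilySpec(f"f{trial}", M=40, conservation=0.8, indel_rate=0.01, seed=trial)
            )
            consensus = "".join(
                "ACDEFGHIKLMNPQRSTVWY"[i] for i in np.argmax(fam.match_emissions, axis=1)
            )
            rng = np.random.default_rng(1000 + trial)
            shuffled = "".join(rng.permutation(list(consensus)))
            a = forward_bitscore(fam, ProteinSequence(id="c", residues=consensus))
            b = forward_bitscore(fam, ProteinSequence(id="s", residues=shuffled))
            wins += a > b
        assert wins >= 18

    def test_unknown_mode_rejected(self, toy_family):
        with pytest.raises(ParameterError):
            forward_bitscore(toy_family, ProteinSequence(id="q", residues="MKV"), mode="hybrid")


class TestBuildProfile:
    def test_pseudocount_emission_formula(self):
        msa = MultipleAlignment(ids=("a", "b", "c", "d"), rows=("MKV",) * 4)
        p = build_profile(msa, pseudocount_weight=5.0)
        assert p.M == 3
        assert p.match_emissions[0, AA_INDEX["M"]] == pytest.approx(
            (4 + 5 * 0.05) / (4 + 5), abs=1e-12
        )

    def test_gappy_column_excluded(self):
        rows = ("M-KV", "M-KV", "MAKV", "MAKV", "M-KV")  # col 1: 3/5 gapped
        msa = MultipleAlignment(ids=tuple("abcde"), rows=rows)
        p = build_profile(msa, gap_threshold=0.5)
        assert p.M == 3

    def test_huge_pseudocount_reverts_to_background(self):
        msa = MultipleAlignment(ids=("a", "b"), rows=("MKV", "MKV"))
        p = build_profile(msa, pseudocount_weight=1e9)
        assert np.allclose(p.match_emissions, p.background, atol=1e-6)

    def test_no_match_column_raises(self):
        msa = MultipleAlignment(ids=("a", "b", "c"), rows=("M--", "-K-", "--V"))
        with pytest.raises(EmptyModelError):
            build_profile(msa, gap_threshold=0.1)

    def test_bad_gap_threshold(self):
        msa = MultipleAlignment(ids=("a", "b"), rows=("MKV", "MKV"))
        with pytest.raises(ParameterError):
            build_profile(msa, gap_threshold=1.5)

    def test_built_profile_is_valid(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        rows = []
        base = rng.choice(letters, size=25)
        for _ in range(8):
            row = base.copy()
            idx = rng.choice(25, size=4, replace=False)
            row[idx] = rng.choice(letters, size=4)
            if rng.random() < 0.5:
                row[rng.integers(25)] = "-"
            rows.append("".join(row))
        msa = MultipleAlignment(ids=tuple(f"s{i}" for i in range(8)), rows=tuple(rows))
        build_profile(msa).validate()  # raises on violation


class TestLocateDomain:
    def test_random_query_has_no_hit(self, toy_family, rng):
        q = random_protein(rng, 100)
        assert locate_domain(toy_family, q, threshold=180.0) is None

    def test_embedded_domain_recovered(self, toy_family):
        rng = np.random.default_rng(7)
        core = sample_sequence(toy_family, rng).residues
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        left = "".join(rng.choice(letters, size=50))
        right = "".join(rng.choice(letters, size=50))
        q = ProteinSequence(id="q", residues=left + core + right)
        hit = locate_domain(toy_family, q, threshold=20.0)
        assert hit is not None
        true_start, true_end = 50, 50 + len(core)
        overlap = max(0, min(hit.end, true_end) - max(hit.start, true_start))
        assert overlap / (true_end - true_start) >= 0.8

    def test_infinitely_low_threshold_always_hits(self, toy_family, rng):
        q = random_protein(rng, 30)
        hit = locate_domain(toy_family, q, threshold=-math.inf)
        assert hit is not None and hit.start < hit.end


class TestSampleSequence:
    def test_deterministic_given_seed(self, toy_family):
        a = sample_sequence(toy_family, np.random.default_rng(7))
        b = sample_sequence(toy_family, np.random.default_rng(7))
        assert a.residues == b.residues

    def test_indel_free_model_emits_exact_length(self):
        fam = make_family_hmm(FamilySpec("rigid", M=25, conservation=0.9,
                                         indel_rate=0.0, seed=1))
        for seed in range(5):
            assert len(sample_sequence(fam, np.random.default_rng(seed))) == 25

    def test_samples_outscore_background_strings(self, toy_family):
        rng = np.random.default_rng(11)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        sample_scores, random_scores = [], []
        for _ in range(50):
            s = sample_sequence(toy_family, rng)
            sample_scores.append(forward_bitscore(toy_family, s))
            r = ProteinSequence(id="r", residues="".join(rng.choice(letters, size=len(s))))
            random_scores.append(forward_bitscore(toy_family, r))
        assert np.mean(sample_scores) > np.mean(random_scores)


class TestSerialization:
    def test_json_round_trip_toy(self):
        hmm = random_model(3, 9)
        back = read_profile_json(write_profile_json(hmm))
        assert np.array_equal(back.match_emissions, hmm.match_emissions)
        assert np.array_equal(back.transitions, hmm.transitions)
        assert np.array_equal(back.background, hmm.background)

    def test_json_round_trip_large(self):
        fam = make_family_hmm(FamilySpec("big", M=400, conservation=0.7, seed=2))
        back = read_profile_json(write_profile_json(fam))
        assert np.array_equal(back.match_emissions, fam.match_emissions)

    def test_tampered_document_rejected(self):
        import json

        doc = json.loads(write_profile_json(random_model(3, 9)))
        doc["match_emissions"] = doc["match_emissions"][:-1]
        with pytest.raises(ValidationError):
            read_profile_json(json.dumps(doc))

    def test_wrong_schema_version(self):
        import json

        doc = json.loads(write_profile_json(random_model(1, 0)))
        doc["version"] = 99
        with pytest.raises(SchemaVersionError):
            read_profile_json(json.dumps(doc))


MINI_HMM = """HMMER3/f [3.4 | Aug 2023]
NAME  mini
LENG  2
ALPH  amino
HMM          A        C        D        E        F        G        H        I        K        L        M        N        P        Q        R        S        T        V        W        Y
            m->m     m->i     m->d     i->m     i->i     d->m     d->d
  COMPO   2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573
          2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573
          0.01005  5.29832  5.29832  0.61904  0.77319  0.00000        *
      1   0.00000        *        *        *        *        *        *        *        *        *        *        *        *        *        *        *        *        *        *        *
          2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573
          0.01005  5.29832  5.29832  0.61904  0.77319  0.48776  0.95166
      2   2.99573  0.00100  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573
          2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573
          0.01005  5.29832        *  0.61904  0.77319  0.48776  0.95166
//
"""


class TestHmmer3Reader:
    def test_value_decoding(self):
        hmm = read_hmmer3_ascii(MINI_HMM)
        assert hmm.M == 2 and hmm.name == "mini"
        # 0.0000 -> probability 1 (then renormalized with the 1e-9 floors)
        assert hmm.match_emissions[0, AA_INDEX["A"]] == pytest.approx(1.0, abs=1e-6)
        # exp(-2.99573) = 0.05
        assert hmm.background[0] == pytest.approx(0.05, abs=1e-5)
        # '*' floors to ~0 and the group renormalizes
        assert hmm.transitions[2, 2] < 1e-6

    def test_round_trip_through_json(self):
        hmm = read_hmmer3_ascii(MINI_HMM)
        back = read_profile_json(write_profile_json(hmm))
        assert np.allclose(back.match_emissions, hmm.match_emissions, atol=1e-12)

    def test_non_amino_alphabet_rejected(self):
        bad = MINI_HMM.replace("ALPH  amino", "ALPH  DNA")
        with pytest.raises(UnsupportedAlphabetError):
            read_hmmer3_ascii(bad)

    def test_malformed_line_reports_number(self):
        bad = MINI_HMM.replace("0.61904", "oops", 1)
        with pytest.raises(ProfileParseError, match="line"):
            read_hmmer3_ascii(bad)

    def test_reads_real_hmmbuild_output(self, tmp_path, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        base = rng.choice(letters, size=40)
        fasta = ""
        for i in range(6):
            row = base.copy()
            idx = rng.choice(40, size=5, replace=False)
            row[idx] = rng.choice(letters, size=5)
            fasta += f">s{i}\n{''.join(row)}\n"
        seed_path = tmp_path / "seed.afa"
        seed_path.write_text(fasta)
        out = tmp_path / "prof.hmm"
        subprocess.run(
            ["hmmbuild", "--amino", str(out), str(seed_path)],
            check=True, capture_output=True,
        )
        hmm = read_hmmer3_ascii(out.read_text())
        hmm.validate()
        assert hmm.M == 40
        consensus = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in np.argmax(hmm.match_emissions, axis=1)
        )
        assert forward_bitscore(hmm, ProteinSequence(id="c", residues=consensus)) > 0


class TestProfileValidation:
    def test_negative_emission_rejected(self):
        hmm = random_model(2, 0)
        bad = hmm.match_emissions.copy()
        bad[0, 0] = -0.1
        bad[0, 1] += 0.1
        with pytest.raises(ValidationError):
            ProfileHMM("bad", bad, hmm.insert_emissions, hmm.transitions, hmm.background)

    def test_transition_rows_must_normalize(self):
        hmm = random_model(2, 0)
        bad = hmm.transitions.copy()
        bad[1, 0] *= 2
        with pytest.raises(ValidationError):
            ProfileHMM("bad", hmm.match_emissions, hmm.insert_emissions, bad, hmm.background)
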