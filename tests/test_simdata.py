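"""Synthetic-data generator: determinism, planted ground truth, and
agreement between emitted files and recorded truth."""

import json
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from seppipe.ions import (
    MONOISOTOPIC,
    PROTON,
    WATER,
    ModifiedPeptide,
    read_mgf,
)
from seppipe.sepdb import build_database, find_orfs, read_transcripts
from seppipe.simdata import (
    GroundTruth,
    SimConfig,
    simulate_abundance,
    simulate_dataset,
    simulate_psm_table,
    simulate_spectra,
    simulate_transcripts,
)


class TestConfig:
    def test_weights_must_sum_to_one(self):
        cfg = SimConfig(start_codon_weights={"ATG": 0.5, "GTG": 0.4})
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()

    def test_length_range_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(sorf_length_range=(5, 50)).validate()
        with pytest.raises(ValueError):
            SimConfig(sorf_length_range=(8, 120)).validate()

    def test_bad_fc(self):
        with pytest.raises(ValueError, match="planted_fc"):
            SimConfig(planted_fc=0.0).validate()


class TestSimulateTranscripts:
    def test_planted_counts_and_lengths(self):
        cfg = SimConfig(seed=1, n_planted_sorfs=10, sorf_length_range=(8, 30),
                        n_transcripts=10, transcript_length=200)
        _, truth = simulate_transcripts(cfg)
        assert len(truth.planted_sorfs) == 10
        assert all(8 <= len(s["protein"]) <= 30 for s in truth.planted_sorfs)

    def test_degenerate_weights_all_atg(self):
        cfg = SimConfig(seed=2, start_codon_weights={"ATG": 1.0},
                        n_transcripts=15, n_planted_sorfs=15)
        _, truth = simulate_transcripts(cfg)
        assert {s["start_codon"] for s in truth.planted_sorfs} == {"ATG"}

    def test_deterministic_bytes(self, tmp_path):
        cfg = SimConfig(seed=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(cfg, d1)
        simulate_dataset(SimConfig(seed=1), d2)
        for name in ("transcripts.fasta", "proteome.fasta", "spectra.mgf",
                     "psms.tsv", "intensities.tsv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_different_seed_differs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(SimConfig(seed=1), d1)
        simulate_dataset(SimConfig(seed=2), d2)
        assert (d1 / "transcripts.fasta").read_bytes() != (d2 / "transcripts.fasta").read_bytes()

    def test_too_short_transcript_names_offender(self):
        cfg = SimConfig(transcript_length=100, sorf_length_range=(60, 100),
                        n_transcripts=3, n_planted_sorfs=3)
        with pytest.raises(ValueError, match="TR0000[1-3]"):
            simulate_transcripts(cfg)

    def test_planted_orfs_recovered_by_caller(self):
        cfg = SimConfig(seed=3, n_transcripts=20, n_planted_sorfs=20)
        transcripts, truth = simulate_transcripts(cfg)
        by_id = {t.id: t for t in transcripts}
        for s in truth.planted_sorfs:
            orfs = find_orfs(by_id[s["transcript_id"]])
            found = [(o.start, o.end, o.protein, o.start_codon) for o in orfs]
            assert (s["start"], s["end"], s["protein"], s["start_codon"]) in found

    def test_start_codon_mixture_chisquare(self):
        weights = {"ATG": 0.44, "GTG": 0.22, "TTG": 0.34}
        cfg = SimConfig(seed=5, n_transcripts=1200, n_planted_sorfs=1200,
                        transcript_length=350, sorf_length_range=(8, 60),
                        start_codon_weights=weights)
        _, truth = simulate_transcripts(cfg)
        counts = {c: 0 for c in weights}
        for s in truth.planted_sorfs:
            counts[s["start_codon"]] += 1
        obs = [counts[c] for c in sorted(weights)]
        exp = [weights[c] * 1200 for c in sorted(weights)]
        _, p = stats.chisquare(obs, exp)
        assert p > 0.01


def brute_force_ladder_recount(pep: ModifiedPeptide, spectrum, tol=0.02):
    """Independent recount: direct residue-sum ladders + linear peak scan,
    then an explicit window scan for the longest consecutive run."""
    masses = [MONOISOTOPIC[aa] for aa in pep.sequence]
    for pos, delta in pep.mods:
        masses[pos] += delta
    n = len(masses)
    present = {"b": set(), "y": set()}
    for i in range(1, n):
        b = sum(masses[:i]) + PROTON
        y = sum(masses[n - i:]) + WATER + PROTON
        if any(abs(mz - b) <= tol for mz in spectrum.mz):
            present["b"].add(i)
        if any(abs(mz - y) <= tol for mz in spectrum.mz):
            present["y"].add(i)
    best = 0
    for series in ("b", "y"):
        for start in range(1, n):
            length = 0
            while start + length in present[series]:
                length += 1
            best = max(best, length)
    return best


class TestSimulateSpectra:
    def _peptides(self, rng, n=10):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        out = []
        for _ in range(n):
            seq = "".join(aas[i] for i in rng.integers(0, 20, size=int(rng.integers(6, 20))))
            out.append((ModifiedPeptide.create(seq), 2))
        return out

    def test_full_coverage_full_run(self, rng):
        cfg = SimConfig(fragment_coverage=1.0, noise_peaks=0)
        peps = self._peptides(rng, 5)
        _, truth = simulate_spectra(peps, cfg, rng)
        for (pep, _), (sid, st) in zip(peps, sorted(truth.items())):
            assert st["run_length"] == len(pep) - 1

    def test_zero_coverage_zero_run(self, rng):
        cfg = SimConfig(fragment_coverage=0.0, noise_peaks=5)
        peps = self._peptides(rng, 5)
        spectra, truth = simulate_spectra(peps, cfg, rng)
        for s in spectra:
            assert len(s.mz) == 5
        for st in truth.values():
            assert st["run_length"] == 0

    def test_run_lengths_match_independent_recount(self, rng):
        cfg = SimConfig(fragment_coverage=0.6, noise_peaks=8, seed=9)
        peps = self._peptides(rng, 20)
        spectra, truth = simulate_spectra(peps, cfg, rng)
        for (pep, _), s in zip(peps, spectra):
            assert truth[s.spectrum_id]["run_length"] == brute_force_ladder_recount(pep, s)

    def test_recorded_ppm_is_realized(self, rng):
        from seppipe.ions import precursor_ppm_error

        cfg = SimConfig(precursor_ppm_sigma=2.0)
        peps = self._peptides(rng, 10)
        spectra, truth = simulate_spectra(peps, cfg, rng)
        for (pep, _), s in zip(peps, spectra):
            assert truth[s.spectrum_id]["ppm"] == pytest.approx(
                precursor_ppm_error(pep, s), abs=1e-9
            )

    def test_empty_peptides_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_spectra([], SimConfig(), rng)

    def test_bad_charge_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_spectra([(ModifiedPeptide("PEPTIDEK"), 0)], SimConfig(), rng)


class TestSimulatePsmTable:
    def test_planted_score_violations(self, rng):
        cfg = SimConfig()
        peps = [(ModifiedPeptide.create("PEPTIDEKR"), 2) for _ in range(20)]
        _, spec_truth = simulate_spectra(peps, SimConfig(fragment_coverage=1.0, noise_peaks=0), rng)
        bad = {"SPEC000003", "SPEC000007"}
        df, psm_truth = simulate_psm_table(spec_truth, cfg, rng, bad_score_ids=bad)
        for sid in spec_truth:
            score = float(df.loc[df.spectrum_id == sid, "score"].iloc[0])
            assert (score <= 20.0) == (sid in bad)
            assert psm_truth[sid]["passes"] == (sid not in bad)
            if sid in bad:
                assert psm_truth[sid]["first_fail"] == "min_score"

    def test_short_peptide_fails_length(self, rng):
        peps = [(ModifiedPeptide.create("PEPTI"), 2)]
        _, spec_truth = simulate_spectra(peps, SimConfig(fragment_coverage=1.0, noise_peaks=0), rng)
        _, psm_truth = simulate_psm_table(spec_truth, SimConfig(), rng)
        assert psm_truth["SPEC000001"]["first_fail"] == "min_peptide_len"

    def test_empty_truth_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_psm_table({}, SimConfig(), rng)


class TestSimulateAbundance:
    def test_matrix_shape(self):
        cfg = SimConfig(seed=1, n_replicates=3)
        m, _ = simulate_abundance(50, cfg)
        assert m.shape == (50, 6)

    def test_null_has_no_planted(self):
        m, planted = simulate_abundance(100, SimConfig(planted_fc=1.0))
        assert planted == {}

    def test_planted_fc_recovered_empirically(self):
        cfg = SimConfig(seed=21, planted_fc=4.0, cv=0.1, frac_de=0.3)
        m, planted = simulate_abundance(300, cfg)
        treat = m[[c for c in m.columns if c.startswith("treatment")]].mean(axis=1)
        ctrl = m[[c for c in m.columns if c.startswith("control")]].mean(axis=1)
        fc = treat / ctrl
        planted_fc = fc.loc[list(planted)]
        assert planted_fc.between(3.0, 5.0).mean() > 0.95
        assert planted_fc.median() == pytest.approx(4.0, rel=0.05)
        null_fc = fc.drop(list(planted))
        assert null_fc.between(0.8, 1.25).all()

    def test_dropout_introduces_missing(self):
        cfg = SimConfig(seed=3, dropout=0.3)
        m, _ = simulate_abundance(100, cfg)
        frac = float(m.isna().to_numpy().mean())
        assert 0.2 < frac < 0.4


class TestDatasetClosure:
    def test_truth_roundtrip_and_files(self, sim_dataset):
        _, outdir, truth = sim_dataset
        loaded = GroundTruth.from_json(outdir / "truth.json")
        assert loaded.expected_final == truth.expected_final
        assert loaded.sep_id_by_protein == truth.sep_id_by_protein
        for name in ("transcripts.fasta", "proteome.fasta", "spectra.mgf",
                     "psms.tsv", "intensities.tsv"):
            assert (Path(outdir) / name).exists()

    def test_database_recovers_all_planted(self, sim_dataset, sim_db):
        _, _, truth = sim_dataset
        proteins = sim_db.proteins
        for s in truth.planted_sorfs:
            assert s["protein"] in proteins

    def test_spectra_file_matches_truth(self, sim_dataset):
        _, outdir, truth = sim_dataset
        spectra = read_mgf(str(outdir / "spectra.mgf"))
        assert {s.spectrum_id for s in spectra} == set(truth.spectrum_truth)

    def test_annotated_seps_are_proteome_substrings(self, sim_dataset):
        from Bio import SeqIO

        _, outdir, truth = sim_dataset
        proteome = [str(r.seq) for r in SeqIO.parse(str(outdir / "proteome.fasta"), "fasta")]
        for protein in truth.annotated_sep_proteins:
            assert any(protein in p for p in proteome)
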