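"""Synthetic inputs with machine-readable ground truth.

Generates stranded transcripts with planted small ORFs (AUG/GUG/UUG starts),
centroided MGF spectra with partial b/y coverage and controlled precursor
ppm error, a PSM table with planted curation violations, an annotated
proteome containing a chosen fraction of the planted peptides, and
3-vs-3 log-normal intensity matrices with planted fold changes.

Everything is driven by one integer seed; identical configurations produce
byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import digest as dg
from . import ions
from . import sepdb
from .ions import ModifiedPeptide, Spectrum, Tolerances

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_transcripts",
    "simulate_spectra",
    "simulate_psm_table",
    "simulate_abundance",
    "simulate_dataset",
]

_STOPS = ("TAA", "TAG", "TGA")

# codon table 11, one deterministic list of codons per residue, stops excluded
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(sepdb._TABLE11.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimConfig:
    seed: int = 1
    n_transcripts: int = 40
    transcript_length: int = 500
    n_planted_sorfs: int = 30
    start_codon_weights: dict[str, float] = field(
        default_factory=lambda: {"ATG": 0.44, "GTG": 0.22, "TTG": 0.34}
    )
    sorf_length_range: tuple[int, int] = (8, 100)
    # spectra
    fragment_coverage: float = 0.9
    fragment_jitter_da: float = 0.003
    precursor_ppm_sigma: float = 0.5
    noise_peaks: int = 10
    precursor_charge: int = 2
    oxidation_prob: float = 0.2
    # planted curation violations (fractions of planted sORFs, disjoint)
    frac_bad_ppm: float = 0.1
    frac_bad_run: float = 0.1
    frac_short_peptide: float = 0.1
    frac_bad_score: float = 0.1
    # annotated proteome
    n_annotated_proteins: int = 20
    annotated_length_range: tuple[int, int] = (120, 300)
    frac_annotated_seps: float = 0.2
    # abundance
    n_replicates: int = 3
    planted_fc: float = 4.0
    frac_de: float = 0.2
    cv: float = 0.1
    dropout: float = 0.0

    def validate(self) -> None:
        total = sum(self.start_codon_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("start_codon_weights must sum to 1")
        if set(self.start_codon_weights) - {"ATG", "GTG", "TTG"}:
            raise ValueError("start codons must be among ATG/GTG/TTG")
        lo, hi = self.sorf_length_range
        if not (8 <= lo <= hi <= 100):
            raise ValueError("sorf_length_range must lie within [8, 100]")
        for name in ("fragment_coverage", "frac_bad_ppm", "frac_bad_run",
                     "frac_short_peptide", "frac_bad_score", "frac_annotated_seps",
                     "frac_de", "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_planted_sorfs > self.n_transcripts:
            raise ValueError("at most one planted sORF per transcript is supported")
        if self.planted_fc <= 0:
            raise ValueError("planted_fc must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least two replicates per group")


@dataclass
class GroundTruth:
    """Everything needed to verify pipeline output without re-deriving it."""

    planted_sorfs: list[dict] = field(default_factory=list)
    annotated_sep_proteins: list[str] = field(default_factory=list)
    spectrum_truth: dict[str, dict] = field(default_factory=dict)
    psm_truth: dict[str, dict] = field(default_factory=dict)
    planted_de: dict[str, float] = field(default_factory=dict)
    expected_final: list[str] = field(default_factory=list)
    sep_id_by_protein: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA20[i] for i in rng.integers(0, len(_AA20), size=length))


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        _CODONS_BY_AA[aa][rng.integers(0, len(_CODONS_BY_AA[aa]))] for aa in protein
    )


def simulate_transcripts(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[sepdb.Transcript], GroundTruth]:
    """Random transcripts with one planted sORF in each of the first
    ``n_planted_sorfs`` transcripts.

    Each planted ORF is preceded by an in-frame stop codon so that it opens
    its inter-stop segment: the ORF caller must recover exactly the planted
    protein.  Background sequence is uniform over ACGT with no guarantee of
    ORF absence; the ground truth is authoritative.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    codons = sorted(cfg.start_codon_weights)
    weights = np.array([cfg.start_codon_weights[c] for c in codons])
    lo, hi = cfg.sorf_length_range
    truth = GroundTruth()
    transcripts: list[sepdb.Transcript] = []
    for i in range(cfg.n_transcripts):
        tid = f"TR{i + 1:05d}"
        seq = list("ACGT"[j] for j in rng.integers(0, 4, size=cfg.transcript_length))
        if i < cfg.n_planted_sorfs:
            length = int(rng.integers(lo, hi + 1))
            window = 3 * length + 6  # guard stop + coding region + stop
            if cfg.transcript_length < window:
                raise ValueError(
                    f"transcript {tid} (length {cfg.transcript_length} nt) too short "
                    f"to host a {length}-aa sORF ({window} nt required)"
                )
            start_codon = codons[rng.choice(len(codons), p=weights)]
            protein = "M" + _random_protein(rng, length - 1)
            coding = start_codon + _reverse_translate(rng, protein[1:])
            guard = _STOPS[rng.integers(0, 3)]
            stop = _STOPS[rng.integers(0, 3)]
            offset = int(rng.integers(0, cfg.transcript_length - window + 1))
            insert = guard + coding + stop
            seq[offset:offset + len(insert)] = insert
            orf_start = offset + 3
            truth.planted_sorfs.append({
                "transcript_id": tid,
                "frame": orf_start % 3,
                "start": orf_start,
                "end": orf_start + 3 * length,
                "start_codon": start_codon,
                "protein": protein,
            })
        transcripts.append(sepdb.Transcript(tid, "".join(seq)))
    return transcripts, truth


def simulate_spectra(
    peptides: Sequence[tuple[ModifiedPeptide, int]],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    ppm_overrides: dict[int, float] | None = None,
    coverage_overrides: dict[int, float] | None = None,
    id_offset: int = 0,
) -> tuple[list[Spectrum], dict[str, dict]]:
    """Simulate one centroided spectrum per (peptide, charge).

    A configurable subset of the theoretical singly-charged b/y peaks is
    emitted (independent Bernoulli per ion), with Gaussian m/z jitter
    clipped inside the fragment tolerance, plus noise peaks kept away from
    any theoretical ion.  The stored truth holds the *realized* longest
    consecutive b/y run and precursor ppm error, both recomputed from the
    emitted spectrum.
    """
    if not peptides:
        raise ValueError("no peptides supplied")
    rng = rng or np.random.default_rng(cfg.seed)
    ppm_overrides = ppm_overrides or {}
    coverage_overrides = coverage_overrides or {}
    tol = Tolerances()
    spectra: list[Spectrum] = []
    truth: dict[str, dict] = {}
    for k, (pep, charge) in enumerate(peptides):
        if charge < 1:
            raise ValueError("charge must be >= 1")
        sid = f"SPEC{id_offset + k + 1:06d}"
        coverage = coverage_overrides.get(k, cfg.fragment_coverage)
        theo = ions.theoretical_ions(pep)
        mzs: list[float] = []
        intens: list[float] = []
        for ion in theo:
            if rng.random() < coverage:
                jitter = float(np.clip(rng.normal(0.0, cfg.fragment_jitter_da),
                                       -0.75 * tol.fragment_da, 0.75 * tol.fragment_da))
                mzs.append(ion.theoretical_mz + jitter)
                intens.append(float(rng.uniform(100.0, 1000.0)))
        theo_mzs = np.array([ion.theoretical_mz for ion in theo])
        added = 0
        while added < cfg.noise_peaks:
            mz = float(rng.uniform(150.0, 1500.0))
            if np.min(np.abs(theo_mzs - mz)) > 3 * tol.fragment_da:
                mzs.append(mz)
                intens.append(float(rng.uniform(1.0, 60.0)))
                added += 1
        ppm = ppm_overrides.get(k, float(rng.normal(0.0, cfg.precursor_ppm_sigma)))
        prec = ions.precursor_mz(pep, charge) * (1.0 + ppm / 1e6)
        spectrum = Spectrum(sid, prec, charge, np.array(mzs), np.array(intens))
        matched = ions.match_spectrum(pep, spectrum, tol)
        truth[sid] = {
            "peptide": pep.sequence,
            "mods": pep.mods_string(),
            "charge": charge,
            "run_length": ions.longest_consecutive_run(matched),
            "ppm": ions.precursor_ppm_error(pep, spectrum),
        }
        spectra.append(spectrum)
    return spectra, truth


def simulate_psm_table(
    spectrum_truth: dict[str, dict],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    bad_score_ids: Iterable[str] = (),
    sep_id_by_spectrum: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Emit a PSM table whose scores violate the score threshold exactly for
    ``bad_score_ids``; the returned truth records, per PSM, the realized
    pass/fail and first violated rule (length -> run -> ppm -> score order)."""
    if not spectrum_truth:
        raise ValueError("no spectrum truth available")
    rng = rng or np.random.default_rng(cfg.seed)
    bad = set(bad_score_ids)
    sep_id_by_spectrum = sep_id_by_spectrum or {}
    rows = []
    psm_truth: dict[str, dict] = {}
    for sid in sorted(spectrum_truth):
        st = spectrum_truth[sid]
        if sid in bad:
            score = float(rng.uniform(5.0, 18.0))
        else:
            score = float(rng.uniform(28.0, 70.0))
        pep = ModifiedPeptide.from_strings(st["peptide"], st["mods"])
        prec = ions.precursor_mz(pep, st["charge"]) * (1.0 + st["ppm"] / 1e6)
        rows.append({
            "spectrum_id": sid,
            "peptide": st["peptide"],
            "mods": st["mods"],
            "charge": st["charge"],
            "score": round(score, 2),
            "precursor_mz": round(prec, 6),
            "sep_ids": sep_id_by_spectrum.get(sid, ""),
        })
        fails = []
        if len(st["peptide"]) < 7:
            fails.append("min_peptide_len")
        if st["run_length"] < 4:
            fails.append("min_consecutive_ions")
        if not abs(st["ppm"]) < 2.0:
            fails.append("max_abs_ppm")
        if not round(score, 2) > 20.0:
            fails.append("min_score")
        psm_truth[sid] = {
            "score": round(score, 2),
            "passes": not fails,
            "first_fail": fails[0] if fails else None,
        }
    return pd.DataFrame(rows), psm_truth


def simulate_abundance(
    n_seps: int,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    sep_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Log-normal 2-group intensity matrix with planted fold changes.

    The underlying log-normal is median-parameterized, so the ratio of
    group medians (and of group means) for a planted row equals
    ``planted_fc`` in expectation; null rows share their group parameters.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    ids = list(sep_ids) if sep_ids is not None else [f"SEP{i + 1:06d}" for i in range(n_seps)]
    if len(ids) != n_seps:
        raise ValueError("sep_ids length does not match n_seps")
    sigma = math.sqrt(math.log(1.0 + cfg.cv ** 2))
    n_de = int(round(cfg.frac_de * n_seps)) if cfg.planted_fc != 1.0 else 0
    de_rows = sorted(rng.permutation(n_seps)[:n_de].tolist())
    cols = [f"treatment_{j + 1}" for j in range(cfg.n_replicates)] + \
           [f"control_{j + 1}" for j in range(cfg.n_replicates)]
    data = np.empty((n_seps, 2 * cfg.n_replicates))
    planted: dict[str, float] = {}
    for i in range(n_seps):
        base = 10.0 ** rng.uniform(6.0, 8.0)
        fc = cfg.planted_fc if i in de_rows else 1.0
        mu_t, mu_c = math.log(base * fc), math.log(base)
        data[i, :cfg.n_replicates] = np.exp(rng.normal(mu_t, sigma, size=cfg.n_replicates))
        data[i, cfg.n_replicates:] = np.exp(rng.normal(mu_c, sigma, size=cfg.n_replicates))
        if fc != 1.0:
            planted[ids[i]] = fc
    if cfg.dropout > 0:
        mask = rng.random(data.shape) < cfg.dropout
        data[mask] = np.nan
    df = pd.DataFrame(data, index=pd.Index(ids, name="sep_id"), columns=cols)
    return df, planted


# ---------------------------------------------------------------------------
# Whole-dataset orchestration


def _select_peptide(protein: str, short: bool, max_missed: int = 2) -> str:
    """Pick a supporting peptide from the tryptic digest of a protein.

    Normally the longest product of 7-30 aa (falling back to the longest
    <=30 aa product); for a planted length violation, a <7 aa product or
    the protein's first six residues.
    """
    products = [p.peptide for p in dg.digest(protein, dg.PROTEASES["trypsin"], max_missed)]
    if short:
        cand = sorted((p for p in products if 2 < len(p) < 7), key=len)
        return cand[-1] if cand else protein[:6]
    cand = sorted((p for p in products if 7 <= len(p) <= 30), key=lambda p: (len(p), p))
    if cand:
        return cand[-1]
    cand = sorted((p for p in products if len(p) >= 7), key=lambda p: (len(p), p))
    if cand:
        return cand[0]
    cand = sorted((p for p in products if len(p) >= 2), key=lambda p: (len(p), p))
    return cand[-1] if cand else protein[:25]


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> GroundTruth:
    """Generate the full synthetic input set for one end-to-end run.

    Writes transcripts.fasta, proteome.fasta, spectra.mgf, psms.tsv,
    intensities.tsv and truth.json into ``outdir``.
    """
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    transcripts, truth = simulate_transcripts(cfg, rng)
    sepdb.write_transcripts(transcripts, out / "transcripts.fasta")

    db = sepdb.build_database(transcripts)
    sep_id_of = {e.protein: e.sep_id for e in db}
    truth.sep_id_by_protein = {
        s["protein"]: sep_id_of[s["protein"]] for s in truth.planted_sorfs
    }

    # --- annotated proteome, embedding a fraction of planted proteins
    n_sorfs = len(truth.planted_sorfs)
    n_embed = int(round(cfg.frac_annotated_seps * n_sorfs))
    embed_rows = sorted(rng.permutation(n_sorfs)[:n_embed].tolist())
    lo, hi = cfg.annotated_length_range
    proteome: dict[str, str] = {}
    for j in range(cfg.n_annotated_proteins):
        proteome[f"ANN{j + 1:04d}"] = "M" + _random_protein(rng, int(rng.integers(lo, hi)) - 1)
    ann_ids = sorted(proteome)
    for r, row in enumerate(embed_rows):
        host = ann_ids[r % len(ann_ids)]
        seq = proteome[host]
        planted_protein = truth.planted_sorfs[row]["protein"]
        pos = int(rng.integers(1, max(2, len(seq) - len(planted_protein))))
        proteome[host] = seq[:pos] + planted_protein + seq[pos:]
        truth.annotated_sep_proteins.append(planted_protein)
    with open(out / "proteome.fasta", "w") as fh:
        for pid in sorted(proteome):
            fh.write(f">{pid}\n")
            seq = proteome[pid]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")

    # --- planted violation assignment (disjoint groups)
    counts = {
        "bad_ppm": int(round(cfg.frac_bad_ppm * n_sorfs)),
        "bad_run": int(round(cfg.frac_bad_run * n_sorfs)),
        "short_peptide": int(round(cfg.frac_short_peptide * n_sorfs)),
        "bad_score": int(round(cfg.frac_bad_score * n_sorfs)),
    }
    perm = rng.permutation(n_sorfs).tolist()
    violation: dict[int, str] = {}
    cursor = 0
    for kind, c in counts.items():
        for row in perm[cursor:cursor + c]:
            violation[row] = kind
        cursor += c

    # --- spectra
    peptides: list[tuple[ModifiedPeptide, int]] = []
    ppm_overrides: dict[int, float] = {}
    coverage_overrides: dict[int, float] = {}
    spectrum_sep: dict[int, str] = {}
    for k, sorf in enumerate(truth.planted_sorfs):
        kind = violation.get(k)
        seq = _select_peptide(sorf["protein"], short=(kind == "short_peptide"))
        var_mods = []
        m_positions = [i for i, aa in enumerate(seq) if aa == "M"]
        if m_positions and rng.random() < cfg.oxidation_prob:
            var_mods.append((m_positions[int(rng.integers(0, len(m_positions)))],
                             ions.OXIDATION))
        pep = ModifiedPeptide.create(seq, var_mods, fixed_cam=True)
        peptides.append((pep, cfg.precursor_charge))
        if kind == "bad_ppm":
            ppm_overrides[k] = float(rng.choice([-1.0, 1.0]) * rng.uniform(3.0, 8.0))
        elif kind == "bad_run":
            coverage_overrides[k] = 0.12
        spectrum_sep[k] = truth.sep_id_by_protein[sorf["protein"]]
    spectra, spec_truth = simulate_spectra(
        peptides, cfg, rng, ppm_overrides, coverage_overrides
    )
    truth.spectrum_truth = spec_truth
    ions.write_mgf(spectra, out / "spectra.mgf")

    # --- PSM table
    bad_score_ids = {f"SPEC{k + 1:06d}" for k, kind in violation.items()
                     if kind == "bad_score"}
    sep_by_spectrum = {f"SPEC{k + 1:06d}": sid for k, sid in spectrum_sep.items()}
    psm_df, psm_truth = simulate_psm_table(spec_truth, cfg, rng, bad_score_ids,
                                           sep_by_spectrum)
    truth.psm_truth = psm_truth
    psm_df.to_csv(out / "psms.tsv", sep="\t", index=False)

    # --- abundance matrix over the planted SEP ids
    planted_ids = sorted(truth.sep_id_by_protein.values())
    abundance, planted_de = simulate_abundance(len(planted_ids), cfg, rng, planted_ids)
    truth.planted_de = planted_de
    abundance.to_csv(out / "intensities.tsv", sep="\t", float_format="%.4f")

    # --- expected final set: novel + >=1 passing PSM with a unique peptide
    annotated = set(truth.annotated_sep_proteins)
    mapping = dg.map_peptides_to_seps(
        {st["peptide"] for st in spec_truth.values()}, db
    )
    expected = set()
    for k, sorf in enumerate(truth.planted_sorfs):
        sid_spec = f"SPEC{k + 1:06d}"
        st, pt = spec_truth[sid_spec], psm_truth[sid_spec]
        protein = sorf["protein"]
        if protein in annotated or not pt["passes"]:
            continue
        if any(protein in p for p in annotated):
            continue
        if mapping.unique.get(st["peptide"]):
            expected.add(truth.sep_id_by_protein[protein])
    truth.expected_final = sorted(expected)

    truth.to_json(out / "truth.json")
    return truth
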