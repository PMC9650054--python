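"""File-level orchestration of the curation stage: read PSMs + spectra +
database + annotated proteome, re-annotate b/y ladders, map peptides, run
the filter funnel and novelty screen, and write the report artifacts."""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import curate, digest as dg, ions
from .curate import CurationReport, CurationThresholds, NoveltyParams, PsmRecord
from .ions import ModifiedPeptide, Tolerances
from .sepdb import SepDatabase, read_database

__all__ = ["load_psm_table", "annotate_psms", "run_curation"]

PSM_REQUIRED_COLUMNS = ("spectrum_id", "peptide", "charge", "score", "precursor_mz")


def load_psm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mods": str, "sep_ids": str})
    for col in PSM_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"PSM table {path} is missing required column {col!r}")
    return df


def annotate_psms(
    psm_table: pd.DataFrame,
    spectra: dict[str, ions.Spectrum],
    tol: Tolerances = Tolerances(),
) -> list[PsmRecord]:
    """Build PSM records with re-annotated run lengths and ppm errors."""
    records: list[PsmRecord] = []
    for row in psm_table.itertuples(index=False):
        mods = getattr(row, "mods", "-")
        pep = ModifiedPeptide.from_strings(row.peptide, mods if isinstance(mods, str) else "-")
        try:
            spectrum = spectra[row.spectrum_id]
        except KeyError:
            raise ValueError(f"spectrum {row.spectrum_id!r} not found in MGF input") from None
        matched = ions.match_spectrum(pep, spectrum, tol)
        records.append(PsmRecord(
            spectrum_id=row.spectrum_id,
            peptide=pep,
            charge=int(row.charge),
            score=float(row.score),
            precursor_mz=float(row.precursor_mz),
            ppm=ions.precursor_ppm_error(pep, spectrum),
            run_length=ions.longest_consecutive_run(matched),
        ))
    return records


def run_curation(
    psms_path: str | Path,
    spectra_path: str | Path,
    db_path: str | Path,
    proteome_path: str | Path,
    outdir: str | Path,
    thresholds: CurationThresholds = CurationThresholds(),
    novelty_params: NoveltyParams = NoveltyParams(),
    max_missed: int = 2,
) -> CurationReport:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    db = read_database(db_path)
    spectra = {s.spectrum_id: s for s in ions.read_mgf(spectra_path)}
    table = load_psm_table(psms_path)
    psms = annotate_psms(table, spectra)

    mapping = dg.map_peptides_to_seps({p.peptide.sequence for p in psms}, db,
                                      max_missed=max_missed)
    for p in psms:
        hits = mapping.hits.get(p.peptide.sequence, {})
        p.sep_ids = sorted(hits)
        p.unique = bool(mapping.unique.get(p.peptide.sequence, False))

    verdicts = curate.filter_psms(psms, thresholds)

    candidates = sorted({sid for p in psms for sid in p.sep_ids})
    sep_seq = {e.sep_id: e.protein for e in db if e.sep_id in set(candidates)}
    peptides_by_sep: dict[str, list[str]] = {}
    for p in psms:
        for sid in p.sep_ids:
            peptides_by_sep.setdefault(sid, []).append(p.peptide.sequence)
    proteome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(proteome_path), "fasta")}
    novelty = curate.novelty_screen(sep_seq, proteome, peptides_by_sep, novelty_params)

    report = curate.assemble_sepome(psms, verdicts, novelty, thresholds, novelty_params)
    report.to_json(out / "curation_report.json")

    with open(out / "sepome.fasta", "w") as fh:
        for sid in sorted(report.final_seps):
            seq = sep_seq[sid]
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(out / "evidence.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sep_id", "peptide", "spectrum_id", "score", "ppm", "run_length", "unique"])
        verdict_by_id = {v.spectrum_id: v for v in verdicts}
        for p in psms:
            if not verdict_by_id[p.spectrum_id].passed:
                continue
            for sid in p.sep_ids:
                if sid in report.final_seps:
                    w.writerow([sid, p.peptide.sequence, p.spectrum_id,
                                f"{p.score:.2f}", f"{p.ppm:.3f}", p.run_length, p.unique])
    return report
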