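"""Curation funnel: PSM-level quality filters, novelty screening against an
annotated proteome, and assembly of the final validated peptide set.

A PSM survives iff its peptide has at least 7 residues, at least 4
consecutive matched b/y ions in one series, absolute precursor error below
2 ppm and a search score above 20 (length/run inclusive, ppm/score strict).
Candidates matching the annotated proteome — by exact peptide substring or
by local alignment above identity/coverage thresholds — are removed; the
final set keeps candidates with at least one passing, unique, novel peptide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .ions import ModifiedPeptide
from .sepdb import SepDatabase

__all__ = [
    "PsmRecord",
    "CurationThresholds",
    "PsmVerdict",
    "AlignmentResult",
    "CurationReport",
    "filter_psms",
    "local_align",
    "novelty_screen",
    "assemble_sepome",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_SUBMAT = np.array(
    [[int(_BLOSUM62[a, b]) for b in _ALPHABET] for a in _ALPHABET], dtype=np.int32
)

# Rule order fixes which violation is reported first; the pass/fail outcome
# is a conjunction and therefore order-invariant.
RULE_ORDER = ("min_peptide_len", "min_consecutive_ions", "max_abs_ppm", "min_score")


@dataclass
class PsmRecord:
    spectrum_id: str
    peptide: ModifiedPeptide
    charge: int
    score: float
    precursor_mz: float
    sep_ids: list[str] = field(default_factory=list)
    ppm: float | None = None
    run_length: int | None = None
    unique: bool | None = None


@dataclass(frozen=True)
class CurationThresholds:
    min_peptide_len: int = 7
    min_consecutive_ions: int = 4
    max_abs_ppm: float = 2.0
    min_score: float = 20.0
    upstream_fdr: float = 0.01  # property of the consumed PSM table, not recomputed

    def __post_init__(self) -> None:
        if min(self.min_peptide_len, self.min_consecutive_ions,
               self.max_abs_ppm, self.min_score) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class PsmVerdict:
    spectrum_id: str
    passed: bool
    first_fail: str | None


def _violations(psm: PsmRecord, t: CurationThresholds) -> list[str]:
    if psm.run_length is None or psm.ppm is None:
        raise ValueError(f"PSM {psm.spectrum_id}: run_length/ppm not populated")
    v = []
    if len(psm.peptide) < t.min_peptide_len:
        v.append("min_peptide_len")
    if psm.run_length < t.min_consecutive_ions:
        v.append("min_consecutive_ions")
    if not abs(psm.ppm) < t.max_abs_ppm:
        v.append("max_abs_ppm")
    if not psm.score > t.min_score:
        v.append("min_score")
    return v


def filter_psms(
    psms: Sequence[PsmRecord], t: CurationThresholds = CurationThresholds()
) -> list[PsmVerdict]:
    """Apply the four PSM rules; record the first violated rule per PSM."""
    verdicts = []
    for psm in psms:
        v = _violations(psm, t)
        verdicts.append(PsmVerdict(psm.spectrum_id, not v, v[0] if v else None))
    return verdicts


# ---------------------------------------------------------------------------
# Local alignment (Smith-Waterman, BLOSUM62, affine gaps).


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    score: int
    identity: float          # percent identical columns over the aligned region
    n_columns: int
    query_start: int         # 0-based half-open span in query
    query_end: int
    subject_start: int
    subject_end: int
    aligned_query: str
    aligned_subject: str

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"non-standard residue {e.args[0]!r} in sequence") from None


def _sw_fill(q, s, submat, gap_open, gap_extend):
    """Fill H/E/F and pointer matrices.  A gap of length L costs
    gap_open + L*gap_extend.  Tie preference in H: diagonal > up > left > stop."""
    n, m = q.shape[0], s.shape[0]
    NEG = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)   # gap in query (left)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)   # gap in subject (up)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)    # 0 stop, 1 diag, 2 up, 3 left
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)    # 1 opened from H, 0 extended
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + submat[qi, s[j - 1]]
            h = 0
            p = 0
            if diag >= h and diag >= F[i, j] and diag >= E[i, j]:
                h = diag
                p = 1
            elif F[i, j] >= h and F[i, j] >= E[i, j]:
                h = F[i, j]
                p = 2
            elif E[i, j] >= h:
                h = E[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, ptrH, ptrE, ptrF, best, bi, bj


try:  # optional JIT; the pure-python kernel is the reference implementation
    from numba import njit as _njit

    _sw_fill_fast = _njit(cache=True)(_sw_fill)
except Exception:  # pragma: no cover
    _sw_fill_fast = _sw_fill


def local_align(
    query: str,
    subject: str,
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment with BLOSUM62 and affine gaps.

    A gap of length L costs ``gap_open + L*gap_extend``.  Traceback is
    deterministic: at equal scores the diagonal move is preferred, then the
    move consuming a query residue, then the move consuming a subject
    residue; the highest-scoring cell is the first one reached in row-major
    order.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    q, s = _encode(query), _encode(subject)
    H, E, F, ptrH, ptrE, ptrF, best, bi, bj = _sw_fill_fast(
        q, s, _SUBMAT, gap_open, gap_extend
    )
    if best <= 0:
        return AlignmentResult(query_id, subject_id, 0, 0.0, 0, 0, 0, 0, 0, "", "")
    aq: list[str] = []
    asub: list[str] = []
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                aq.append(query[i - 1])
                asub.append(subject[j - 1])
                i -= 1
                j -= 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            opened = ptrF[i, j]
            aq.append(query[i - 1])
            asub.append("-")
            i -= 1
            if opened:
                state = "H"
        else:  # E
            opened = ptrE[i, j]
            aq.append("-")
            asub.append(subject[j - 1])
            j -= 1
            if opened:
                state = "H"
    aq.reverse()
    asub.reverse()
    n_cols = len(aq)
    matches = sum(1 for a, b in zip(aq, asub) if a == b and a != "-")
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=int(best),
        identity=100.0 * matches / n_cols if n_cols else 0.0,
        n_columns=n_cols,
        query_start=i,
        query_end=bi,
        subject_start=j,
        subject_end=bj,
        aligned_query="".join(aq),
        aligned_subject="".join(asub),
    )


# ---------------------------------------------------------------------------
# Novelty screen


@dataclass(frozen=True)
class NoveltyParams:
    identity_threshold: float = 90.0   # percent, over the aligned region
    coverage_threshold: float = 0.8    # fraction of the candidate aligned
    kmer_size: int = 4
    use_prefilter: bool = True


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def novelty_screen(
    seps: Mapping[str, str],
    proteome: Mapping[str, str],
    peptides_by_sep: Mapping[str, Iterable[str]] | None = None,
    params: NoveltyParams = NoveltyParams(),
) -> dict[str, str]:
    """Classify each candidate as ``novel`` or ``matches_annotated``.

    A candidate matches the annotated proteome if any supporting peptide is
    an exact substring of an annotated protein, or if the candidate aligns
    to one with identity >= ``identity_threshold`` over at least
    ``coverage_threshold`` of its length.  The k-mer prefilter only skips
    alignments that cannot reach the thresholds; it never changes statuses.
    """
    if not proteome:
        raise ValueError("annotated proteome is empty")
    index: dict[str, set[str]] = {}
    if params.use_prefilter:
        for pid, pseq in proteome.items():
            for km in _kmers(pseq, params.kmer_size):
                index.setdefault(km, set()).add(pid)
    status: dict[str, str] = {}
    for sep_id, sep_seq in seps.items():
        peptides = list(peptides_by_sep.get(sep_id, [])) if peptides_by_sep else []
        matched = False
        for pid, pseq in proteome.items():
            if sep_seq in pseq or any(pep in pseq for pep in peptides):
                matched = True
                break
        if not matched:
            if params.use_prefilter:
                cands = set()
                for km in _kmers(sep_seq, params.kmer_size):
                    cands |= index.get(km, set())
            else:
                cands = set(proteome)
            min_span = params.coverage_threshold * len(sep_seq)
            for pid in sorted(cands):
                aln = local_align(sep_seq, proteome[pid], query_id=sep_id, subject_id=pid)
                if aln.identity >= params.identity_threshold and aln.query_span >= min_span:
                    matched = True
                    break
        status[sep_id] = "matches_annotated" if matched else "novel"
    return status


# ---------------------------------------------------------------------------
# Funnel assembly


@dataclass
class CurationReport:
    thresholds: CurationThresholds
    novelty_params: NoveltyParams
    verdicts: list[PsmVerdict]
    sep_status: dict[str, str]       # novel / matches_annotated / insufficient_evidence
    funnel: dict[str, int]           # stage -> surviving candidate count
    final_seps: dict[str, list[str]]  # sep_id -> supporting passing unique peptides

    def to_json(self, path: str) -> None:
        payload = {
            "thresholds": asdict(self.thresholds),
            "novelty_params": asdict(self.novelty_params),
            "funnel": self.funnel,
            "sep_status": self.sep_status,
            "psm_verdicts": [asdict(v) for v in self.verdicts],
            "final_seps": self.final_seps,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def assemble_sepome(
    psms: Sequence[PsmRecord],
    verdicts: Sequence[PsmVerdict],
    novelty: Mapping[str, str],
    thresholds: CurationThresholds = CurationThresholds(),
    novelty_params: NoveltyParams = NoveltyParams(),
) -> CurationReport:
    """Combine the funnel stages into the final set with per-stage counts.

    Stage order: database hit -> known-protein removal -> PSM filters ->
    uniqueness -> final.  A candidate reaches the final set iff it is novel
    and has at least one passing, unique peptide.
    """
    verdict_by_id = {v.spectrum_id: v for v in verdicts}
    candidates = sorted({sid for p in psms for sid in p.sep_ids})
    after_novelty = [s for s in candidates if novelty.get(s, "novel") == "novel"]

    def _seps_with(pred) -> list[str]:
        keep = set()
        for p in psms:
            if pred(p):
                keep.update(p.sep_ids)
        return [s for s in after_novelty if s in keep]

    passing = {p.spectrum_id for p in psms if verdict_by_id[p.spectrum_id].passed}
    after_filter = _seps_with(lambda p: p.spectrum_id in passing)
    after_unique = _seps_with(lambda p: p.spectrum_id in passing and p.unique)

    final: dict[str, list[str]] = {}
    for p in psms:
        if p.spectrum_id in passing and p.unique:
            for sid in p.sep_ids:
                if sid in after_unique:
                    final.setdefault(sid, [])
                    if p.peptide.sequence not in final[sid]:
                        final[sid].append(p.peptide.sequence)

    status = dict(novelty)
    for s in candidates:
        if status.get(s) == "novel" and s not in final:
            status[s] = "insufficient_evidence"

    funnel = {
        "database_hit": len(candidates),
        "after_known_protein_removal": len(after_novelty),
        "after_psm_filters": len(after_filter),
        "after_uniqueness": len(after_unique),
        "final": len(final),
    }
    return CurationReport(thresholds, novelty_params, list(verdicts), status, funnel, final)
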