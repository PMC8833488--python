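"""Maximum-entropy 3' (acceptor) splice-site scoring and de novo scanning.

The acceptor model scores a 23-mer window: positions 1-20 are intronic, with
the obligate AG dinucleotide at positions 19-20, and positions 21-23 are the
first exonic bases.  The score is the log2 odds of the window under a
maximum-entropy distribution of real acceptor sites versus a background
composition model:

    MES = log2( P_cons(AG positions) / P_bgd(AG positions)
                * P_maxent(21 non-AG positions) / P_bgd(21 non-AG positions) )

P_maxent over the 21 remaining positions is combined from nine lower-order
marginal tables by inclusion-exclusion: five 7-mer marginals over position
blocks {1-7}, {8-14}, {15-21}, {5-11}, {12-18} multiplied together, divided
by the four marginals over their pairwise overlaps {5-7}, {8-11}, {12-14},
{15-18}.  This is the decomposition used by the published maximum-entropy
acceptor model, whose distributed table files this loader reads.

Scores are deterministic; a window without AG at positions 19-20 can still
be scored (a damaged canonical site), but the de novo scanner only proposes
windows satisfying the obligate AG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

_NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(_NT)}

# numerator blocks (start, length) within the 21-mer of non-AG positions,
# then denominator (overlap) blocks — the inclusion-exclusion layout.
_NUMERATOR_BLOCKS = ((0, 7), (7, 7), (14, 7), (4, 7), (11, 7))
_DENOMINATOR_BLOCKS = ((4, 3), (7, 4), (11, 3), (14, 4))
SUBMODEL_BLOCKS = _NUMERATOR_BLOCKS + _DENOMINATOR_BLOCKS
#: file stems of the nine submodel tables, in combination order
SUBMODEL_FILES = tuple(f"me2x3acc{i}" for i in range(1, 10))

NORMALIZATION_TOL = 1e-6


class SpliceModelError(ValueError):
    pass


@dataclass(frozen=True)
class MESModel:
    """Loaded maximum-entropy acceptor model (23-mer site kind)."""

    background: dict[str, float]  # composition over ACGT
    cons1: dict[str, float]  # position 19 (the A of the obligate AG)
    cons2: dict[str, float]  # position 20 (the G)
    submodels: tuple[tuple[float, ...], ...]  # nine tables, 4**k entries each
    site_kind: str = "acceptor23"

    def __post_init__(self) -> None:
        if len(self.submodels) != len(SUBMODEL_BLOCKS):
            raise SpliceModelError("expected nine submodel tables")
        for table, (_, k) in zip(self.submodels, SUBMODEL_BLOCKS):
            if len(table) != 4**k:
                raise SpliceModelError(
                    f"submodel table has {len(table)} entries, expected {4 ** k}"
                )
            if abs(sum(table) - 1.0) > NORMALIZATION_TOL:
                raise SpliceModelError("submodel table does not normalize to 1")
        for probs in (self.background, self.cons1, self.cons2):
            if set(probs) != set(_NT):
                raise SpliceModelError("probability table must cover ACGT")
            if abs(sum(probs.values()) - 1.0) > NORMALIZATION_TOL:
                raise SpliceModelError("probability table does not normalize to 1")


@dataclass(frozen=True)
class SpliceSiteCall:
    sequence_window: str
    genomic_offset: int  # relative to the canonical 3' intron end
    mes_score: float
    label: str  # "canonical" | "de_novo"


def kmer_index(kmer: str) -> int:
    """Row index of a k-mer in a table file (A<C<G<T, first base most
    significant) — the published positional layout."""
    idx = 0
    for c in kmer:
        idx = idx * 4 + _NT_INDEX[c]
    return idx


def _read_probs_file(path: Path, expected: int) -> tuple[float, ...]:
    try:
        values = [float(line.split()[-1]) for line in path.read_text().split("\n") if line.strip()]
    except (OSError, ValueError) as exc:
        raise SpliceModelError(f"cannot read model table {path}: {exc}") from exc
    if len(values) != expected:
        raise SpliceModelError(
            f"model table {path} has {len(values)} rows, expected {expected}"
        )
    return tuple(values)


def _read_nt_probs(path: Path) -> dict[str, float]:
    probs: dict[str, float] = {}
    try:
        for line in path.read_text().split("\n"):
            if not line.strip():
                continue
            nt, val = line.split()
            probs[nt.upper()] = float(val)
    except (OSError, ValueError) as exc:
        raise SpliceModelError(f"cannot read probability table {path}: {exc}") from exc
    return probs


def load_mes_acceptor_model(model_dir: str | Path) -> MESModel:
    """Load the acceptor model from a directory of table files.

    Layout: ``bgd`` (4 rows ``NT prob``), ``cons1``/``cons2`` (4 rows each,
    the obligate-AG position distributions) and ``me2x3acc1``..``me2x3acc9``
    (one probability per row, row order = lexicographic k-mer index).  A
    ``.txt`` suffix on any file is accepted.
    """
    model_dir = Path(model_dir)

    def find(stem: str) -> Path:
        for cand in (model_dir / stem, model_dir / f"{stem}.txt"):
            if cand.exists():
                return cand
        raise SpliceModelError(f"missing model table {stem!r} in {model_dir}")

    submodels = tuple(
        _read_probs_file(find(stem), 4**k)
        for stem, (_, k) in zip(SUBMODEL_FILES, SUBMODEL_BLOCKS)
    )
    return MESModel(
        background=_read_nt_probs(find("bgd")),
        cons1=_read_nt_probs(find("cons1")),
        cons2=_read_nt_probs(find("cons2")),
        submodels=submodels,
    )


def uniform_mes_model() -> MESModel:
    """Synthetic uniform model: every 23-mer scores exactly 0."""
    flat = {c: 0.25 for c in _NT}
    submodels = tuple(
        tuple([1.0 / 4**k] * 4**k) for (_, k) in SUBMODEL_BLOCKS
    )
    return MESModel(background=dict(flat), cons1=dict(flat), cons2=dict(flat), submodels=submodels)


def _validate_window(seq: str) -> str:
    seq = seq.upper()
    if len(seq) != 23:
        raise ValueError(f"acceptor window must be 23 nt, got {len(seq)}")
    if any(c not in _NT_INDEX for c in seq):
        raise ValueError(f"acceptor window contains non-ACGT characters: {seq}")
    return seq


def score_acceptor(seq23: str, model: MESModel) -> float:
    """MES (log2 odds) of a 23-mer under the acceptor model."""
    seq = _validate_window(seq23)
    cons_ratio = (
        model.cons1[seq[18]]
        * model.cons2[seq[19]]
        / (model.background[seq[18]] * model.background[seq[19]])
    )
    rest = seq[:18] + seq[20:]  # the 21 non-AG positions
    log_me = 0.0
    for table, (start, k), sign in zip(
        model.submodels,
        SUBMODEL_BLOCKS,
        (1, 1, 1, 1, 1, -1, -1, -1, -1),
    ):
        log_me += sign * math.log2(table[kmer_index(rest[start : start + k])])
    log_bgd = sum(math.log2(model.background[c]) for c in rest)
    return math.log2(cons_ratio) + log_me - log_bgd


def scan_de_novo_acceptors(
    sequence: str,
    canonical_end: int,
    window_radius: int,
    model: MESModel,
) -> list[SpliceSiteCall]:
    """Score candidate acceptor sites around a canonical 3' intron end.

    ``canonical_end`` is the 0-based index in ``sequence`` of the last
    intronic base (the G of the canonical AG).  Every offset in
    ``[-window_radius, +window_radius]`` whose window carries AG at the
    obligate positions is scored; the canonical offset 0 is labelled
    ``canonical``.  Calls are sorted by descending score (ties by distance
    from the canonical site, then upstream first).
    """
    sequence = sequence.upper()
    calls: list[SpliceSiteCall] = []
    for offset in range(-window_radius, window_radius + 1):
        end = canonical_end + offset  # index of the G
        start = end - 19
        stop = end + 4  # 3 exonic bases
        if start < 0 or stop > len(sequence):
            raise ValueError(
                f"window at offset {offset:+d} exceeds the provided sequence"
            )
        window = sequence[start:stop]
        if window[18:20] != "AG":
            continue
        calls.append(
            SpliceSiteCall(
                sequence_window=window,
                genomic_offset=offset,
                mes_score=score_acceptor(window, model),
                label="canonical" if offset == 0 else "de_novo",
            )
        )
    calls.sort(key=lambda c: (-c.mes_score, abs(c.genomic_offset), c.genomic_offset))
    return calls


class UnsupportedSpliceOutcome(ValueError):
    """Alternative-site geometry outside the supported model (upstream or
    intronic de novo sites imply skipping/retention, which we do not guess)."""


def predict_splice_outcome(
    canonical: Optional[SpliceSiteCall],
    de_novo: Optional[SpliceSiteCall],
    exon_cds_start: int,
):
    """Transcript edit implied by switching to a downstream de novo acceptor.

    A de novo acceptor ``k`` nucleotides downstream of the canonical site
    removes the first ``k`` exonic nucleotides of the affected exon:
    with the exon starting at coding position ``exon_cds_start`` the result
    is a deletion of ``c.exon_cds_start .. exon_cds_start+k-1``.  Offset 0
    (canonical site used) yields no edit.  Upstream alternatives are not
    modelled.
    """
    from .protein import TranscriptEdit  # local import; protein is standalone

    offset = 0 if de_novo is None else de_novo.genomic_offset
    if canonical is not None:
        offset -= canonical.genomic_offset
    if offset == 0:
        return TranscriptEdit(kind="none", cds_start=exon_cds_start, cds_end=exon_cds_start)
    if offset < 0:
        raise UnsupportedSpliceOutcome(
            f"de novo acceptor {offset:+d} is upstream of the canonical site"
        )
    return TranscriptEdit(
        kind="del",
        cds_start=exon_cds_start,
        cds_end=exon_cds_start + offset - 1,
    )
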