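"""Transcript edits and HGVS protein consequences (frameshift fs*N calls).

Given a coding sequence and a small edit (deletion/insertion in CDS
coordinates), translate both alleles and derive the HGVS protein-level
description.  The fs*N convention counts the termination codon with the
first changed residue as codon 1, so a truncation "17 codons downstream"
of the first changed residue is ``fs*17``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqUtils import seq3


class EditError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptEdit:
    """An edit in 1-based inclusive CDS coordinates.

    ``del``: remove cds_start..cds_end.  ``ins``: insert ``inserted`` after
    cds_start (cds_end == cds_start).  ``delins``: replace the range with
    ``inserted``.  ``none``: no change.
    """

    kind: str  # del | ins | delins | none
    cds_start: int
    cds_end: int
    inserted: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("del", "ins", "delins", "none"):
            raise EditError(f"unknown edit kind {self.kind!r}")
        if self.cds_start < 1 or self.cds_end < self.cds_start:
            raise EditError("bad edit coordinates")
        if self.kind in ("ins", "delins") and not self.inserted:
            raise EditError(f"{self.kind} edit requires inserted sequence")

    @property
    def length_change(self) -> int:
        if self.kind == "none":
            return 0
        removed = 0 if self.kind == "ins" else self.cds_end - self.cds_start + 1
        return len(self.inserted) - removed


@dataclass(frozen=True)
class ProteinConsequence:
    hgvs_p: str
    category: str  # frameshift | nonsense | inframe_del | inframe_ins | synonymous | no_stop
    first_changed_codon: Optional[int] = None
    stop_offset: Optional[int] = None  # the N of fs*N


def apply_edit(cds: str, edit: TranscriptEdit) -> str:
    cds = cds.upper()
    if edit.kind == "none":
        return cds
    if edit.cds_end > len(cds):
        raise EditError(
            f"edit end {edit.cds_end} beyond CDS length {len(cds)}"
        )
    start, end = edit.cds_start - 1, edit.cds_end  # 0-based half-open
    if edit.kind == "del":
        return cds[:start] + cds[end:]
    if edit.kind == "ins":
        return cds[: edit.cds_start] + edit.inserted.upper() + cds[edit.cds_start :]
    return cds[:start] + edit.inserted.upper() + cds[end:]


def _translate(cds: str) -> str:
    """Amino acids up to and including the first stop ('*'); trailing
    partial codons are ignored."""
    usable = len(cds) - len(cds) % 3
    aa = str(Seq(cds[:usable]).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[: stop + 1]


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def protein_consequence(cds: str, edit: TranscriptEdit) -> ProteinConsequence:
    """Translate the reference and edited CDS and name the difference.

    Frameshifts are reported as ``p.<Wt><pos><Mut>fs*<N>`` with N the
    position of the new-frame stop counting the first changed codon as 1;
    a first changed codon that is itself a stop is a nonsense call
    ``p.<Wt><pos>Ter``; in-frame edits give del/ins/delins notation; a
    shifted frame that never reaches a stop is flagged ``no_stop``.
    """
    cds = cds.upper()
    if len(cds) < 6:
        raise EditError("CDS shorter than 6 nt")
    if not cds.startswith("ATG"):
        warnings.warn("CDS does not start with ATG; proceeding", stacklevel=2)
    mutant_cds = apply_edit(cds, edit)

    wt = _translate(cds)
    mut = _translate(mutant_cds)
    if wt == mut:
        return ProteinConsequence(hgvs_p="p.(=)", category="synonymous")

    # first codon whose amino acid differs (or where one allele runs out)
    pos = None
    for i in range(max(len(wt), len(mut))):
        a = wt[i] if i < len(wt) else None
        b = mut[i] if i < len(mut) else None
        if a != b:
            pos = i
            break
    assert pos is not None
    wt_aa = wt[pos] if pos < len(wt) else "*"
    frameshift = edit.length_change % 3 != 0

    if frameshift:
        if pos >= len(mut):
            # edited allele ends before a new stop is reached
            return ProteinConsequence(
                hgvs_p=f"p.{_aa3(wt_aa)}{pos + 1}fs*?",
                category="no_stop",
                first_changed_codon=pos + 1,
            )
        mut_aa = mut[pos]
        if mut_aa == "*":
            return ProteinConsequence(
                hgvs_p=f"p.{_aa3(wt_aa)}{pos + 1}Ter",
                category="nonsense",
                first_changed_codon=pos + 1,
            )
        if not mut.endswith("*"):
            return ProteinConsequence(
                hgvs_p=f"p.{_aa3(wt_aa)}{pos + 1}{_aa3(mut_aa)}fs*?",
                category="no_stop",
                first_changed_codon=pos + 1,
            )
        stop_offset = len(mut) - pos  # stop codon counting pos as 1
        return ProteinConsequence(
            hgvs_p=f"p.{_aa3(wt_aa)}{pos + 1}{_aa3(mut_aa)}fs*{stop_offset}",
            category="frameshift",
            first_changed_codon=pos + 1,
            stop_offset=stop_offset,
        )

    # in-frame: prefer a clean deletion/insertion reading before nonsense
    n_codons = abs(edit.length_change) // 3
    if edit.length_change < 0 and wt[:pos] + wt[pos + n_codons :] == mut:
        last = min(pos + n_codons - 1, len(wt) - 1)
        if n_codons == 1:
            hgvs = f"p.{_aa3(wt[pos])}{pos + 1}del"
        else:
            hgvs = f"p.{_aa3(wt[pos])}{pos + 1}_{_aa3(wt[last])}{last + 1}del"
        return ProteinConsequence(
            hgvs_p=hgvs, category="inframe_del", first_changed_codon=pos + 1
        )
    if edit.length_change > 0 and mut[:pos] + mut[pos + n_codons :] == wt:
        ins3 = "".join(_aa3(a) for a in mut[pos : pos + n_codons])
        return ProteinConsequence(
            hgvs_p=f"p.{_aa3(wt[pos - 1]) if pos else 'Met'}{pos}_"
            f"{_aa3(wt_aa)}{pos + 1}ins{ins3}",
            category="inframe_ins",
            first_changed_codon=pos + 1,
        )
    if pos < len(mut) and mut[pos] == "*":
        return ProteinConsequence(
            hgvs_p=f"p.{_aa3(wt_aa)}{pos + 1}Ter",
            category="nonsense",
            first_changed_codon=pos + 1,
        )
    # residual in-frame change: delins notation, categorised by net length
    end_wt = len(wt) - 1
    hgvs = f"p.{_aa3(wt_aa)}{pos + 1}_{_aa3(wt[end_wt])}{end_wt + 1}delins..."
    category = "inframe_del" if edit.length_change <= 0 else "inframe_ins"
    return ProteinConsequence(
        hgvs_p=hgvs, category=category, first_changed_codon=pos + 1
    )
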