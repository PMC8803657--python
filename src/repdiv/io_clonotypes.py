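"""Clonotype-table I/O and the core domain types.

Two dialects are supported: AIRR Rearrangement TSV (columns ``junction``,
``junction_aa``, ``v_call``, ``d_call``, ``j_call``, ``duplicate_count``,
optionally ``productive``) and a MiXCR-style export (``cloneCount``,
``nSeqCDR3``, ``aaSeqCDR3``, ``allVHitsWithScore``, ...).  Rows are merged
on the clonotype key ``(cdr3_nt, v_gene, j_gene)`` by summing UMI counts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from repdiv.errors import FormatError, RowValidationError

__all__ = [
    "Clonotype",
    "Repertoire",
    "clonotype_key",
    "normalize_gene_name",
    "read_airr",
    "read_mixcr",
    "translate_nt",
    "write_airr",
]

# Standard genetic code as a flat codon->residue dict; '*' marks stops.
_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_GENE_RE = re.compile(r"^TR[ABGD][VDJ]", re.IGNORECASE)


def translate_nt(nt: str) -> str:
    """Translate an in-frame nucleotide string with the standard code.

    Raises ``ValueError`` if the length is not a multiple of 3 or a codon
    contains a non-ACGT character.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    try:
        return "".join(CODON_TO_AA[nt[i : i + 3]] for i in range(0, len(nt), 3))
    except KeyError as exc:
        raise ValueError(f"invalid codon {exc.args[0]!r}") from None


def normalize_gene_name(raw: str) -> str:
    """Normalize a V/D/J segment name.

    Strips allele suffixes (``*01``), anything after ``(`` (MiXCR scores),
    maps ``.`` family separators to ``-`` and upper-cases.  Idempotent.
    Names that do not look like a TR segment are kept verbatim (after the
    same cosmetic transforms) with a warning — never dropped silently.
    """
    name = raw.strip()
    if not name:
        raise ValueError("empty gene name")
    name = name.split("(")[0].split("*")[0].strip()
    name = name.replace(".", "-").upper()
    if not _GENE_RE.match(name):
        warnings.warn(f"unparseable gene name kept verbatim: {raw!r}", stacklevel=2)
    return name


@dataclass(frozen=True)
class Clonotype:
    """One rearranged TRB species: CDR3 sequences, gene calls, UMI count."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    d_gene: str = ""
    count: int = 1
    productive: bool = True

    def __post_init__(self):
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if self.productive:
            if len(self.cdr3_nt) % 3 != 0:
                raise ValueError(
                    f"productive clonotype with junction length {len(self.cdr3_nt)} "
                    "not divisible by 3"
                )
            aa = translate_nt(self.cdr3_nt.upper())
            if aa != self.cdr3_aa:
                raise ValueError(
                    f"cdr3_aa {self.cdr3_aa!r} does not match translation {aa!r}"
                )
            if "*" in self.cdr3_aa:
                raise ValueError("productive clonotype contains a stop codon")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cdr3_nt, self.v_gene, self.j_gene)


def clonotype_key(ct: Clonotype, key_mode: str = "nt_vj"):
    """Species definition used by overlap/usage analyses.

    ``nt`` — CDR3 nucleotide sequence only; ``nt_vj`` — nucleotide + V + J;
    ``aa`` — CDR3 amino-acid sequence.
    """
    if key_mode == "nt":
        return ct.cdr3_nt
    if key_mode == "nt_vj":
        return (ct.cdr3_nt, ct.v_gene, ct.j_gene)
    if key_mode == "aa":
        return ct.cdr3_aa
    raise ValueError(f"unknown key_mode {key_mode!r}; expected nt, nt_vj or aa")


@dataclass
class Repertoire:
    """A sample's clonotype collection plus metadata.

    ``clonotypes`` is keyed by ``(cdr3_nt, v_gene, j_gene)``; construction
    through :meth:`from_clonotypes` merges duplicate keys by summing counts,
    so keys are unique and ``total_count`` equals the sum of member counts
    by construction.
    """

    sample_id: str
    clonotypes: dict[tuple[str, str, str], Clonotype] = field(default_factory=dict)
    group: str = "other"
    subset: str = "other"

    @classmethod
    def from_clonotypes(
        cls,
        sample_id: str,
        clonotypes,
        group: str = "other",
        subset: str = "other",
    ) -> "Repertoire":
        merged: dict[tuple[str, str, str], Clonotype] = {}
        for ct in clonotypes:
            k = ct.key
            if k in merged:
                merged[k] = replace(merged[k], count=merged[k].count + ct.count)
            else:
                merged[k] = ct
        return cls(sample_id=sample_id, clonotypes=merged, group=group, subset=subset)

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __iter__(self):
        return iter(self.clonotypes.values())

    @property
    def richness(self) -> int:
        return len(self.clonotypes)

    @property
    def total_count(self) -> int:
        return sum(ct.count for ct in self.clonotypes.values())

    @property
    def counts(self) -> np.ndarray:
        return np.array([ct.count for ct in self.clonotypes.values()], dtype=np.int64)

    @property
    def frequencies(self) -> np.ndarray:
        c = self.counts
        return c / c.sum()

    def key_counts(self, key_mode: str = "nt_vj") -> dict:
        """Counts aggregated under the requested species definition."""
        out: dict = {}
        for ct in self.clonotypes.values():
            k = clonotype_key(ct, key_mode)
            out[k] = out.get(k, 0) + ct.count
        return out

    def key_frequencies(self, key_mode: str = "nt_vj") -> dict:
        kc = self.key_counts(key_mode)
        total = sum(kc.values())
        return {k: v / total for k, v in kc.items()}


def _is_productive_row(nt: str, aa: str) -> bool:
    if len(nt) % 3 != 0:
        return False
    try:
        return translate_nt(nt) == aa and "*" not in aa
    except ValueError:
        return False


_AIRR_REQUIRED = ["junction", "junction_aa", "v_call", "j_call", "duplicate_count"]


def read_airr(
    path,
    productive_only: bool = True,
    sample_id: str | None = None,
    group: str = "other",
    subset: str = "other",
) -> Repertoire:
    """Read an AIRR Rearrangement TSV into a validated :class:`Repertoire`.

    Rows sharing the clonotype key are merged by summing ``duplicate_count``.
    When ``productive_only`` (the default), out-of-frame or stop-containing
    junctions are dropped.  Gene names are normalized.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _AIRR_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing mandatory AIRR column {col!r} in {path}")
    if sample_id is None:
        sample_id = str(path)

    clonotypes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        nt = str(getattr(row, "junction")).upper()
        aa = str(getattr(row, "junction_aa"))
        try:
            count = int(getattr(row, "duplicate_count"))
        except ValueError:
            raise RowValidationError(
                f"non-integer duplicate_count {getattr(row, 'duplicate_count')!r}", line=i
            ) from None
        if count < 1:
            raise RowValidationError(f"non-positive count {count}", line=i)
        if "productive" in df.columns:
            productive = str(getattr(row, "productive")).strip().upper() in ("T", "TRUE", "1")
        else:
            productive = _is_productive_row(nt, aa)
        if productive_only and not productive:
            continue
        d_raw = str(getattr(row, "d_call", "")) if "d_call" in df.columns else ""
        clonotypes.append(
            Clonotype(
                cdr3_nt=nt,
                cdr3_aa=aa,
                v_gene=normalize_gene_name(getattr(row, "v_call")),
                j_gene=normalize_gene_name(getattr(row, "j_call")),
                d_gene=normalize_gene_name(d_raw) if d_raw.strip() else "",
                count=count,
                productive=productive,
            )
        )
    return Repertoire.from_clonotypes(sample_id, clonotypes, group=group, subset=subset)


_AIRR_COLUMNS = [
    "junction",
    "junction_aa",
    "v_call",
    "d_call",
    "j_call",
    "duplicate_count",
    "productive",
]


def write_airr(rep: Repertoire, path) -> None:
    """Write a Repertoire as AIRR TSV; ``read_airr`` round-trips exactly."""
    rows = [
        {
            "junction": ct.cdr3_nt,
            "junction_aa": ct.cdr3_aa,
            "v_call": ct.v_gene,
            "d_call": ct.d_gene,
            "j_call": ct.j_gene,
            "duplicate_count": ct.count,
            "productive": "T" if ct.productive else "F",
        }
        for ct in rep
    ]
    df = pd.DataFrame(rows, columns=_AIRR_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


_MIXCR_REQUIRED = ["cloneCount", "nSeqCDR3", "aaSeqCDR3", "allVHitsWithScore", "allJHitsWithScore"]


def _best_hit(field_value: str) -> str:
    """First hit of a MiXCR multi-hit field, stripped of score and allele."""
    first = str(field_value).split(",")[0].strip()
    return first


def read_mixcr(
    path,
    productive_only: bool = True,
    sample_id: str | None = None,
    group: str = "other",
    subset: str = "other",
) -> Repertoire:
    """Read a MiXCR/miTCR-style clone table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _MIXCR_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing mandatory MiXCR column {col!r} in {path}")
    if sample_id is None:
        sample_id = str(path)

    clonotypes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        nt = str(getattr(row, "nSeqCDR3")).upper()
        aa = str(getattr(row, "aaSeqCDR3"))
        count = int(float(getattr(row, "cloneCount")))
        if count < 1:
            raise RowValidationError(f"non-positive count {count}", line=i)
        productive = _is_productive_row(nt, aa)
        if productive_only and not productive:
            continue
        d_raw = (
            _best_hit(getattr(row, "allDHitsWithScore"))
            if "allDHitsWithScore" in df.columns
            else ""
        )
        clonotypes.append(
            Clonotype(
                cdr3_nt=nt,
                cdr3_aa=aa,
                v_gene=normalize_gene_name(_best_hit(getattr(row, "allVHitsWithScore"))),
                j_gene=normalize_gene_name(_best_hit(getattr(row, "allJHitsWithScore"))),
                d_gene=normalize_gene_name(d_raw) if d_raw.strip() else "",
                count=count,
                productive=productive,
            )
        )
    return Repertoire.from_clonotypes(sample_id, clonotypes, group=group, subset=subset)
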