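"""Structured tDR nomenclature: format and parse names like ``tDR-1:33-Glu-CTC-1-M2``.

A tDR name encodes, in order: the fragment boundaries on its source
transcript (plain integers for mature positions, ``T<i>``/``L<i>`` for
precursor trailer/leader positions), the isodecoder it maps to
(isotype-anticodon-transcript number, plus a gene-copy token for
precursor-derived fragments), a ``-M<k>`` suffix when the fragment maps
equally well to k >= 2 isodecoders, and trailing variant codes for
misincorporations (``A1G`` = fragment position 1, reference A observed G)
or deletions (``D5G`` = reference base G deleted at fragment position 5).

Variant positions are 1-based relative to the fragment's first base, not to
the transcript.  Isoacceptor-level names without a transcript number (e.g.
``tDR-1:36-Glu-TTC``) are accepted and re-emitted as written.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["VariantCode", "TDRName", "format_name", "parse_name", "ParseError"]

_LABEL_RE = re.compile(r"^(?:\d+|[TL]\d+)$")
_SUB_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")
_DEL_RE = re.compile(r"^D(\d+)([ACGT])$")
_M_RE = re.compile(r"^M(\d+)$")
_ISOTYPE_RE = re.compile(r"^[A-Za-z]{3,4}$")
_ANTICODON_RE = re.compile(r"^[ACGT]{3}$")


class ParseError(ValueError):
    """A tDR name that does not conform to the grammar."""

    def __init__(self, name: str, pos: int, message: str):
        self.name = name
        self.pos = pos
        super().__init__(f"cannot parse {name!r} at token {pos}: {message}")


@dataclass(frozen=True, order=True)
class VariantCode:
    kind: str  # "substitution" | "deletion"
    position: int  # 1-based, relative to the fragment's first base
    ref_base: str
    obs_base: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "deletion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("variant position must be >= 1")
        if self.kind == "substitution":
            if self.obs_base is None or self.obs_base == self.ref_base:
                raise ValueError("substitution requires obs_base != ref_base")
        elif self.obs_base is not None:
            raise ValueError("deletion carries no observed base")

    def __str__(self) -> str:
        if self.kind == "substitution":
            return f"{self.ref_base}{self.position}{self.obs_base}"
        return f"D{self.position}{self.ref_base}"

    @classmethod
    def from_token(cls, token: str) -> "VariantCode":
        m = _SUB_RE.match(token)
        if m and m.group(1) != m.group(3):
            return cls("substitution", int(m.group(2)), m.group(1), m.group(3))
        m = _DEL_RE.match(token)
        if m:
            return cls("deletion", int(m.group(1)), m.group(2))
        raise ValueError(f"not a variant code: {token!r}")


def _label_key(label: str) -> tuple[int, int]:
    # order: leader (most 5') < body < trailer
    if label.startswith("L"):
        return (0, -int(label[1:]))
    if label.startswith("T"):
        return (2, int(label[1:]))
    return (1, int(label))


@dataclass(frozen=True)
class TDRName:
    """Parsed tDR name; ``str()`` re-emits the canonical form."""

    start_label: str
    end_label: str
    isotype: str
    anticodon: str
    transcript_no: int | None = None
    gene_copy: int | None = None
    multimap_k: int = 1
    variants: tuple[VariantCode, ...] = ()

    def __post_init__(self) -> None:
        for lab in (self.start_label, self.end_label):
            if not _LABEL_RE.match(lab):
                raise ValueError(f"bad position label {lab!r}")
        if _label_key(self.start_label) > _label_key(self.end_label):
            raise ValueError(
                f"start {self.start_label} lies 3' of end {self.end_label}"
            )
        if self.multimap_k < 1:
            raise ValueError("multimap_k must be >= 1")
        if self.gene_copy is not None and self.transcript_no is None:
            raise ValueError("a gene-copy token requires a transcript number")

    @property
    def is_precursor(self) -> bool:
        return any(
            lab[0] in "TL" for lab in (self.start_label, self.end_label)
        )

    def __str__(self) -> str:
        parts = [
            "tDR",
            f"{self.start_label}:{self.end_label}",
            self.isotype,
            self.anticodon,
        ]
        if self.transcript_no is not None:
            parts.append(str(self.transcript_no))
        if self.gene_copy is not None:
            parts.append(str(self.gene_copy))
        if self.multimap_k >= 2:
            parts.append(f"M{self.multimap_k}")
        parts.extend(str(v) for v in self.variants)
        return "-".join(parts)


def parse_name(s: str) -> TDRName:
    """Parse a tDR name string into its structured form.

    Accepts ``:`` or ``-`` between the start and end labels (both appear in
    print); Unicode hyphens are normalized.  Raises :class:`ParseError`
    naming the offending token on malformed input.
    """
    if not s:
        raise ParseError(s, 0, "empty string")
    norm = s.replace("‐", "-").replace("‑", "-").replace("–", "-")
    tokens = norm.split("-")
    if tokens[0] != "tDR":
        raise ParseError(s, 0, "must start with 'tDR-'")
    tokens = tokens[1:]
    if not tokens:
        raise ParseError(s, 1, "nothing after 'tDR-'")

    # boundaries: either one token "start:end" or two hyphen-separated tokens
    if ":" in tokens[0]:
        start, _, end = tokens[0].partition(":")
        rest = tokens[1:]
    else:
        if len(tokens) < 2:
            raise ParseError(s, 1, "missing end label")
        start, end = tokens[0], tokens[1]
        rest = tokens[2:]
    for i, lab in enumerate((start, end)):
        if not _LABEL_RE.match(lab):
            raise ParseError(s, 1 + i, f"bad position label {lab!r}")

    if len(rest) < 2:
        raise ParseError(s, 2, "missing isotype/anticodon")
    isotype, anticodon, *rest = rest
    if not _ISOTYPE_RE.match(isotype):
        raise ParseError(s, 3, f"bad isotype {isotype!r}")
    if not _ANTICODON_RE.match(anticodon):
        raise ParseError(s, 4, f"bad anticodon {anticodon!r}")

    transcript_no: int | None = None
    gene_copy: int | None = None
    ints = []
    while rest and rest[0].isdigit():
        ints.append(int(rest.pop(0)))
    if len(ints) > 2:
        raise ParseError(s, 5, "too many numeric tokens")
    if ints:
        transcript_no = ints[0]
    if len(ints) == 2:
        gene_copy = ints[1]

    multimap_k = 1
    if rest and _M_RE.match(rest[0]):
        multimap_k = int(rest.pop(0)[1:])

    variants = []
    for tok_idx, tok in enumerate(rest):
        try:
            variants.append(VariantCode.from_token(tok))
        except ValueError:
            raise ParseError(s, 6 + tok_idx, f"unrecognized token {tok!r}") from None

    try:
        return TDRName(
            start_label=start,
            end_label=end,
            isotype=isotype,
            anticodon=anticodon,
            transcript_no=transcript_no,
            gene_copy=gene_copy,
            multimap_k=multimap_k,
            variants=tuple(variants),
        )
    except ValueError as exc:
        raise ParseError(s, 0, str(exc)) from None


def format_name(
    start_label: str | int,
    end_label: str | int,
    isotype: str,
    anticodon: str,
    transcript_no: int | None,
    gene_copy: int | None = None,
    multimap_k: int = 1,
    variants: tuple[VariantCode, ...] = (),
) -> str:
    """Canonical tDR name string for a fragment (see :class:`TDRName`)."""
    return str(
        TDRName(
            start_label=str(start_label),
            end_label=str(end_label),
            isotype=isotype,
            anticodon=anticodon,
            transcript_no=transcript_no,
            gene_copy=gene_copy,
            multimap_k=multimap_k,
            variants=tuple(variants),
        )
    )
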