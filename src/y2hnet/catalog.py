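"""Merged yeast two-hybrid interactor catalogs.

A binary Y2H screen is run in two orientations: the bait fused to the Gal4
DNA-binding domain against an activation-domain ORF library (``DB_BAIT``),
and the reverse (``AD_BAIT``).  Each orientation yields a hit list; the
analysis object is the union catalog keyed by Entrez Gene ID, carrying per
partner the screen orientation(s) it was found in, whether the interaction
was previously described, whether it was confirmed by affinity
co-purification, and where in the cell a bimolecular fluorescence
complementation (BiFC) assay placed the interaction.

Gene identity is keyed on Entrez Gene ID rather than symbol, because symbol
cells carry parenthesized aliases (e.g. ``"ADAMTSL4 (TSRC1)"``) that would
break naive joins.
"""
from __future__ import annotations

import enum
import io as _stdio
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "COMPARTMENTS",
    "Catalog",
    "Copurification",
    "InteractorRecord",
    "LocalizationCall",
    "LocalizationParseError",
    "MergeConflictError",
    "ProteinRef",
    "ScreenConfig",
    "merge_screens",
    "parse_localization",
    "read_catalog_tsv",
    "summarize_counts",
    "tally_localization",
]

#: Subcellular compartments distinguished by the BiFC signal column.
COMPARTMENTS: tuple[str, ...] = ("nuclear", "cytoplasmic", "vesicular")


class ScreenConfig(enum.Enum):
    """Orientation of the two-hybrid screen a hit came from."""

    DB_BAIT = "DB"  # bait-DB fusion vs AD-ORF library
    AD_BAIT = "AD"  # bait-AD fusion vs DB-ORF library


class Copurification(enum.Enum):
    """Outcome of the orthogonal affinity co-purification validation."""

    CONFIRMED = "Y"
    NOT_CONFIRMED = "N"


class LocalizationParseError(ValueError):
    """A BiFC-signal cell contained an unrecognized token."""


class MergeConflictError(ValueError):
    """The two screen hit lists disagree on a shared protein's annotations."""


@dataclass(frozen=True)
class LocalizationCall:
    """Outcome of the BiFC localization assay for one interactor.

    Exactly one of three variants:

    * a compartment *pattern* — non-empty subset of :data:`COMPARTMENTS`;
    * *no signal* (the table's ``/`` sentinel) — assayed, nothing seen;
    * *not determined* (``n.d.``) — not assayed or not scoreable.
    """

    kind: str  # "pattern" | "no_signal" | "not_determined"
    compartments: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("pattern", "no_signal", "not_determined"):
            raise ValueError(f"unknown localization kind {self.kind!r}")
        if self.kind == "pattern":
            if not self.compartments:
                raise ValueError("pattern localization needs >=1 compartment")
            bad = self.compartments - set(COMPARTMENTS)
            if bad:
                raise ValueError(f"unknown compartments {sorted(bad)}")
        elif self.compartments:
            raise ValueError(f"{self.kind} carries no compartments")

    @classmethod
    def pattern(cls, *compartments: str) -> "LocalizationCall":
        return cls("pattern", frozenset(compartments))

    @classmethod
    def no_signal(cls) -> "LocalizationCall":
        return cls("no_signal")

    @classmethod
    def not_determined(cls) -> "LocalizationCall":
        return cls("not_determined")

    @property
    def is_pattern(self) -> bool:
        return self.kind == "pattern"


_TOKEN_MAP = {
    "nuclear": "nuclear",
    "cytoplasmic": "cytoplasmic",
    "vesicular": "vesicular",
}


def parse_localization(text: str) -> LocalizationCall:
    """Parse a raw BiFC-signal cell into a :class:`LocalizationCall`.

    The tables write patterns inconsistently ("Nuclear and cytoplasmic",
    "Nuclear, vesicular, cytoplasmic", "Nuclear, and vesicular"); commas and
    the word "and" are treated identically as separators, matching is
    case-insensitive, and repeated tokens collapse.  ``/`` means no signal,
    ``n.d.`` not determined.

    Raises
    ------
    LocalizationParseError
        If the cell is empty after trimming or contains a token that is not
        a known compartment.
    """
    stripped = text.strip()
    if not stripped:
        raise LocalizationParseError("empty localization cell")
    if stripped == "/":
        return LocalizationCall.no_signal()
    if stripped.lower() in ("n.d.", "n.d"):
        return LocalizationCall.not_determined()
    tokens = [
        t
        for t in re.split(r"[,\s]+", stripped.lower())
        if t and t != "and"
    ]
    compartments = set()
    for tok in tokens:
        if tok not in _TOKEN_MAP:
            raise LocalizationParseError(
                f"unrecognized localization token {tok!r} in {text!r}"
            )
        compartments.add(_TOKEN_MAP[tok])
    return LocalizationCall("pattern", frozenset(compartments))


@dataclass(frozen=True)
class ProteinRef:
    """A protein keyed by Entrez Gene ID.

    ``symbol`` is the primary gene symbol (first token of the table cell);
    parenthesized aliases are kept in ``aliases``.
    """

    symbol: str
    entrez_id: int
    uniprot_acc: str | None = None
    name: str | None = None
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("symbol must be non-empty")
        if self.entrez_id <= 0:
            raise ValueError("entrez_id must be a positive integer")


@dataclass(frozen=True)
class InteractorRecord:
    """One partner protein of the bait, with its screen bookkeeping.

    ``claimed_overlap`` carries the fixture's explicit both-orientations
    mark when present; it is validated against (never trusted over) the
    overlap derived from ``configs``.
    """

    protein: ProteinRef
    configs: frozenset[ScreenConfig]
    previously_described: bool = False
    copurification: Copurification = Copurification.NOT_CONFIRMED
    bifc: LocalizationCall = LocalizationCall.not_determined()
    function_note: str = ""
    claimed_overlap: bool | None = None

    def __post_init__(self) -> None:
        if not self.configs:
            raise ValueError("configs must be non-empty")

    @property
    def overlap(self) -> bool:
        """True iff the partner was found in both screen orientations."""
        return len(self.configs) == 2


@dataclass(frozen=True)
class Catalog:
    """Union catalog of all partners of one bait, keyed by Entrez Gene ID."""

    bait: ProteinRef
    records: Mapping[int, InteractorRecord]

    def __post_init__(self) -> None:
        for entrez_id, rec in self.records.items():
            if rec.protein.entrez_id != entrez_id:
                raise ValueError(
                    f"record keyed {entrez_id} holds protein "
                    f"{rec.protein.entrez_id}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def partner_records(self, include_bait_self: bool) -> list[InteractorRecord]:
        """Records, optionally dropping the bait's homodimer entry."""
        return [
            rec
            for eid, rec in sorted(self.records.items())
            if include_bait_self or eid != self.bait.entrez_id
        ]


def _check_unique(records: Iterable[InteractorRecord], label: str) -> None:
    seen: set[int] = set()
    for rec in records:
        eid = rec.protein.entrez_id
        if eid in seen:
            raise ValueError(f"duplicate entrez_id {eid} in {label} hit list")
        seen.add(eid)


def _merge_pair(a: InteractorRecord, b: InteractorRecord) -> InteractorRecord:
    """Merge the two orientations' records for the same protein."""
    eid = a.protein.entrez_id
    if a.previously_described != b.previously_described:
        raise MergeConflictError(
            f"previously_described conflict for entrez_id {eid}"
        )
    if a.copurification != b.copurification:
        raise MergeConflictError(f"copurification conflict for entrez_id {eid}")
    if a.bifc != b.bifc:
        raise MergeConflictError(f"BiFC localization conflict for entrez_id {eid}")
    claimed: bool | None
    claims = {c for c in (a.claimed_overlap, b.claimed_overlap) if c is not None}
    if len(claims) > 1:
        raise MergeConflictError(f"overlap-mark conflict for entrez_id {eid}")
    claimed = claims.pop() if claims else None
    return replace(
        a,
        configs=a.configs | b.configs,
        function_note=a.function_note or b.function_note,
        claimed_overlap=claimed,
    )


def merge_screens(
    db_hits: Iterable[InteractorRecord],
    ad_hits: Iterable[InteractorRecord],
    bait: ProteinRef,
) -> Catalog:
    """Union the two orientations' hit lists into a :class:`Catalog`.

    Proteins found in both orientations get their ``configs`` unioned; their
    annotation fields (previously described, co-purification, BiFC) must
    agree, otherwise a :class:`MergeConflictError` is raised.  The overlap
    flag is always derived from ``configs``; an explicit fixture mark that
    contradicts the derived flag is an error.
    """
    db_hits = list(db_hits)
    ad_hits = list(ad_hits)
    _check_unique(db_hits, "DB")
    _check_unique(ad_hits, "AD")
    merged: dict[int, InteractorRecord] = {
        rec.protein.entrez_id: rec for rec in db_hits
    }
    for rec in ad_hits:
        eid = rec.protein.entrez_id
        if eid in merged:
            merged[eid] = _merge_pair(merged[eid], rec)
        else:
            merged[eid] = rec
    for eid, rec in merged.items():
        if rec.claimed_overlap is not None and rec.claimed_overlap != rec.overlap:
            raise MergeConflictError(
                f"entrez_id {eid}: fixture overlap mark "
                f"({rec.claimed_overlap}) contradicts derived configs "
                f"({sorted(c.value for c in rec.configs)})"
            )
    return Catalog(bait=bait, records=dict(sorted(merged.items())))


def summarize_counts(
    catalog: Catalog, include_bait_self: bool
) -> dict[str, int]:
    """Headline counts over a catalog.

    The screen's published conventions mix two counting rules: distinct
    partners exclude the bait homodimer entry while validation and BiFC
    counts include it, so the homodimer handling is an explicit argument.

    Returns a dict with ``n_partners`` (distinct records), ``n_overlap``
    (found in both orientations), ``n_confirmed`` (co-purification
    confirmed), ``n_bifc_positive`` (a compartment pattern was observed),
    plus per-orientation totals ``n_db_config`` and ``n_ad_config``.
    """
    if not catalog.records:
        raise ValueError("catalog is empty")
    recs = catalog.partner_records(include_bait_self)
    return {
        "n_partners": len(recs),
        "n_overlap": sum(r.overlap for r in recs),
        "n_confirmed": sum(
            r.copurification is Copurification.CONFIRMED for r in recs
        ),
        "n_bifc_positive": sum(r.bifc.is_pattern for r in recs),
        "n_db_config": sum(ScreenConfig.DB_BAIT in r.configs for r in recs),
        "n_ad_config": sum(ScreenConfig.AD_BAIT in r.configs for r in recs),
    }


def tally_localization(
    catalog: Catalog, include_bait_self: bool
) -> pd.DataFrame:
    """Per-compartment interaction tallies.

    For each compartment ``c``: ``n_any`` counts records whose BiFC pattern
    contains ``c`` and ``n_exclusive`` those whose pattern is exactly
    ``{c}``.  No-signal and not-determined records contribute to neither.
    """
    if not catalog.records:
        raise ValueError("catalog is empty")
    recs = catalog.partner_records(include_bait_self)
    rows = {}
    for comp in COMPARTMENTS:
        patterns = [r.bifc for r in recs if r.bifc.is_pattern]
        rows[comp] = {
            "n_any": sum(comp in p.compartments for p in patterns),
            "n_exclusive": sum(p.compartments == {comp} for p in patterns),
        }
    return pd.DataFrame.from_dict(rows, orient="index")[
        ["n_any", "n_exclusive"]
    ]


_MARK_PREV = "*"
_MARK_OVERLAP = "§"


def _parse_symbol_cell(cell: str) -> tuple[str, tuple[str, ...], bool, bool]:
    """Split a symbol cell into (symbol, aliases, star-mark, section-mark)."""
    raw = cell.strip()
    prev = False
    claimed = False
    # marks trail the symbol token, possibly before the alias parenthesis
    while raw and raw[-1] in (_MARK_PREV, _MARK_OVERLAP):
        if raw[-1] == _MARK_PREV:
            prev = True
        else:
            claimed = True
        raw = raw[:-1].rstrip()
    aliases = tuple(re.findall(r"\(([^)]*)\)", raw))
    head = raw.split("(", 1)[0].strip()
    token = head.split()[0] if head.split() else ""
    mark_in_token = ""
    while token and token[-1] in (_MARK_PREV, _MARK_OVERLAP):
        mark_in_token += token[-1]
        token = token[:-1]
    for m in mark_in_token:
        if m == _MARK_PREV:
            prev = True
        else:
            claimed = True
    return token, aliases, prev, claimed


def read_catalog_tsv(source) -> list[InteractorRecord]:
    """Read one screen's hit list from the packaged TSV fixture format.

    Columns: symbol, entrez_id, uniprot_acc, name, function_note, configs
    (semicolon-joined DB/AD), previously_described (0/1), copurification
    (Y/N), bifc (verbatim table cell).  The symbol cell may carry a ``*``
    (previously described) and/or ``§`` (both orientations) mark; the ``*``
    must agree with the 0/1 column and the ``§`` claim is retained for
    validation during :func:`merge_screens`.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(
            _stdio.StringIO(source.read()), sep="\t", dtype=str,
            keep_default_na=False,
        )
    records = []
    for i, row in df.iterrows():
        symbol, aliases, star, claimed = _parse_symbol_cell(row["symbol"])
        prev_col = bool(int(row["previously_described"]))
        if star != prev_col:
            raise ValueError(
                f"row {i + 2}: '*' mark ({star}) disagrees with "
                f"previously_described column ({prev_col})"
            )
        configs = frozenset(
            ScreenConfig(tok) for tok in row["configs"].split(";") if tok
        )
        records.append(
            InteractorRecord(
                protein=ProteinRef(
                    symbol=symbol,
                    entrez_id=int(row["entrez_id"]),
                    uniprot_acc=row["uniprot_acc"] or None,
                    name=row["name"] or None,
                    aliases=aliases,
                ),
                configs=configs,
                previously_described=prev_col,
                copurification=Copurification(row["copurification"]),
                bifc=parse_localization(row["bifc"]),
                function_note=row["function_note"],
                claimed_overlap=claimed,
            )
        )
    return records
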