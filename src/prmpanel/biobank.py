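"""Candidate-biomarker bank assembly.

Merges accession lists from three evidence routes — tissue differential
proteins, serum differential proteins, and literature-reported candidates —
into one bank with per-entry provenance, then restricts it to candidates
plausibly measurable in serum.  Serum detectability for tissue/literature
entries is an input annotation (e.g. derived upstream from secretion or
cellular-component prediction); serum-evidenced entries are detectable by
construction.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

PROVENANCES = ("tissue_DEP", "serum_DEP", "literature")
_ISOFORM_SUFFIX = re.compile(r"-\d+$")


def normalize_accession(accession: str) -> str:
    """Uppercase and strip isoform suffixes ('P02768-2' -> 'P02768')."""
    return _ISOFORM_SUFFIX.sub("", accession.strip().upper())


@dataclass
class BankEntry:
    accession: str
    symbol: str = ""
    provenance: set[str] = field(default_factory=set)
    serum_detectable: bool | None = None
    direction: str = ""

    def __post_init__(self) -> None:
        unknown = self.provenance - set(PROVENANCES)
        if unknown:
            raise ValueError(f"unknown provenance {sorted(unknown)}")


@dataclass
class OverlapReport:
    list_sizes: dict[str, int]
    pairwise_overlap: dict[tuple[str, str], int]
    total_overlap: int  # accessions present in more than one list
    union_size: int


Bank = dict[str, BankEntry]


def merge_bank(
    lists: Mapping[str, Iterable[str]],
    provenance_of: Mapping[str, str] | None = None,
    symbols: Mapping[str, str] | None = None,
) -> tuple[Bank, OverlapReport]:
    """Union of named accession lists with merged provenance.

    ``lists`` maps a list name to accessions; ``provenance_of`` maps the
    list name to one of tissue_DEP / serum_DEP / literature (defaults to
    the list name itself).  Merge order does not affect the result.
    """
    if not lists:
        raise ValueError("at least one accession list is required")
    provenance_of = provenance_of or {name: name for name in lists}

    normalized: dict[str, set[str]] = {}
    for name, accs in lists.items():
        prov = provenance_of[name]
        if prov not in PROVENANCES:
            raise ValueError(f"list {name!r} has unknown provenance {prov!r}")
        normalized[name] = {normalize_accession(a) for a in accs}

    bank: Bank = {}
    for name in sorted(normalized):
        prov = provenance_of[name]
        for acc in sorted(normalized[name]):
            entry = bank.setdefault(acc, BankEntry(accession=acc))
            entry.provenance.add(prov)
            if symbols and acc in symbols:
                entry.symbol = symbols[acc]

    pairwise = {
        (a, b): len(normalized[a] & normalized[b])
        for a, b in itertools.combinations(sorted(normalized), 2)
    }
    membership_counts = pd.Series(
        [sum(acc in s for s in normalized.values()) for acc in bank]
    )
    report = OverlapReport(
        list_sizes={name: len(s) for name, s in normalized.items()},
        pairwise_overlap=pairwise,
        total_overlap=int((membership_counts > 1).sum()),
        union_size=len(bank),
    )
    # Inclusion–exclusion sanity check against the plain set union.
    assert report.union_size == len(set().union(*normalized.values()))
    return bank, report


def annotate_serum_detectable(bank: Bank, flags: Mapping[str, bool]) -> Bank:
    """Attach serum-detectability flags (input annotations) to entries."""
    for acc, entry in bank.items():
        if acc in flags:
            entry.serum_detectable = bool(flags[acc])
    return bank


def filter_serum_detectable(bank: Bank) -> Bank:
    """Keep serum-evidenced entries plus flagged-detectable ones.

    An entry survives iff serum_DEP is in its provenance (detected in serum
    directly) or its serum_detectable annotation is True.  Entries lacking
    the annotation (and without serum evidence) are an error, listed by
    accession.
    """
    unflagged = [
        acc for acc, e in bank.items()
        if "serum_DEP" not in e.provenance and e.serum_detectable is None
    ]
    if unflagged:
        raise ValueError(
            f"serum_detectable flag missing for accessions: {sorted(unflagged)[:10]}"
        )
    return {
        acc: e
        for acc, e in bank.items()
        if "serum_DEP" in e.provenance or e.serum_detectable
    }


def write_bank(bank: Bank, path) -> None:
    rows = [
        (e.accession, e.symbol, ";".join(sorted(e.provenance)),
         "" if e.serum_detectable is None else str(e.serum_detectable), e.direction)
        for e in sorted(bank.values(), key=lambda e: e.accession)
    ]
    pd.DataFrame(
        rows, columns=["accession", "symbol", "provenance", "serum_detectable", "direction"]
    ).to_csv(path, sep="\t", index=False)


def read_bank(path) -> Bank:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    bank: Bank = {}
    for _, row in df.iterrows():
        flag = row.get("serum_detectable", "")
        bank[row["accession"]] = BankEntry(
            accession=row["accession"],
            symbol=row.get("symbol", ""),
            provenance=set(filter(None, row["provenance"].split(";"))),
            serum_detectable=None if flag == "" else flag == "True",
            direction=row.get("direction", ""),
        )
    return bank
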