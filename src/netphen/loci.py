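"""Locus panel definitions and configuration IO.

A panel is an ordered collection of biallelic SNP loci. Each locus carries
two independent positions: its position in the closed genotype cycle (the
order in which loci are visited when a subject's genotype is drawn as a
polygon) and its reporting position (the column order used for haplotype
strings). The two orders are independent because the cycle order is a
modelling choice while the reporting order follows publication convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "LocusSpec",
    "validate_loci",
    "cycle_order",
    "report_order",
    "read_loci_config",
    "write_loci_config",
    "ctla4_loci",
]


@dataclass(frozen=True)
class LocusSpec:
    """One biallelic SNP locus.

    Parameters
    ----------
    name : short label used as the genotype-table column name, e.g. ``"AG49"``.
    rsid : dbSNP identifier, used to match VCF records.
    major_allele, minor_allele : single nucleotide characters.
    cycle_position : 0-based position of the locus in the closed cycle.
    report_position : 0-based column position for haplotype strings.
    """

    name: str
    rsid: str
    major_allele: str
    minor_allele: str
    cycle_position: int
    report_position: int

    def __post_init__(self) -> None:
        if self.major_allele == self.minor_allele:
            raise ValueError(
                f"locus {self.name!r}: major and minor alleles are identical "
                f"({self.major_allele!r})"
            )
        for allele in (self.major_allele, self.minor_allele):
            if len(allele) != 1 or allele.upper() not in "ACGT":
                raise ValueError(
                    f"locus {self.name!r}: invalid allele {allele!r}"
                )

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.major_allele, self.minor_allele))


def validate_loci(loci: Sequence[LocusSpec]) -> tuple[LocusSpec, ...]:
    """Validate a panel: unique names, both position fields permutations of 0..L-1."""
    loci = tuple(loci)
    if len(loci) < 3:
        raise ValueError(f"a panel needs at least 3 loci, got {len(loci)}")
    names = [l.name for l in loci]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate locus names in panel: {sorted(names)}")
    n = len(loci)
    for field in ("cycle_position", "report_position"):
        positions = sorted(getattr(l, field) for l in loci)
        if positions != list(range(n)):
            raise ValueError(
                f"{field} values must be a permutation of 0..{n - 1}, got {positions}"
            )
    return loci


def cycle_order(loci: Sequence[LocusSpec]) -> tuple[LocusSpec, ...]:
    """Loci sorted by cycle position (the order they are visited in the cycle)."""
    return tuple(sorted(loci, key=lambda l: l.cycle_position))


def report_order(loci: Sequence[LocusSpec]) -> tuple[LocusSpec, ...]:
    """Loci sorted by report position (haplotype-string column order)."""
    return tuple(sorted(loci, key=lambda l: l.report_position))


def _spec_from_mapping(entry: dict) -> LocusSpec:
    try:
        return LocusSpec(
            name=str(entry["name"]),
            rsid=str(entry.get("rsid", "")),
            major_allele=str(entry["major"]).upper(),
            minor_allele=str(entry["minor"]).upper(),
            cycle_position=int(entry["cycle_position"]),
            report_position=int(entry["report_position"]),
        )
    except KeyError as exc:
        raise ValueError(f"loci config entry missing field {exc}") from exc


def read_loci_config(path: str | Path) -> tuple[LocusSpec, ...]:
    """Read a loci panel from a YAML or JSON file.

    The file holds a list of mappings with keys
    ``name, rsid, major, minor, cycle_position, report_position``
    (optionally nested under a top-level ``loci`` key).
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if isinstance(data, dict) and "loci" in data:
        data = data["loci"]
    if not isinstance(data, list):
        raise ValueError(f"loci config {path}: expected a list of locus entries")
    return validate_loci([_spec_from_mapping(e) for e in data])


def write_loci_config(loci: Iterable[LocusSpec], path: str | Path) -> None:
    entries = [
        {
            "name": l.name,
            "rsid": l.rsid,
            "major": l.major_allele,
            "minor": l.minor_allele,
            "cycle_position": l.cycle_position,
            "report_position": l.report_position,
        }
        for l in loci
    ]
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(entries, indent=2))
    else:
        path.write_text(yaml.safe_dump(entries, sort_keys=False))


def ctla4_loci() -> tuple[LocusSpec, ...]:
    """The six-SNP CTLA-4 panel.

    Cycle order CT318, AG49, CT60, JO30, JO27, JO31 (the hexagon closes
    JO31 back to CT318); report order AG49, CT60, CT318, JO27, JO30, JO31,
    so the all-major haplotype string reads ``AACCAT``.
    """
    return validate_loci(
        [
            LocusSpec("CT318", "rs5742909", "C", "T", 0, 2),
            LocusSpec("AG49", "rs231775", "A", "G", 1, 0),
            LocusSpec("CT60", "rs3087243", "A", "G", 2, 1),
            LocusSpec("JO30", "rs7565213", "A", "G", 3, 4),
            LocusSpec("JO27", "rs11571297", "C", "T", 4, 3),
            LocusSpec("JO31", "rs11571302", "T", "G", 5, 5),
        ]
    )
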