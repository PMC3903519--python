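"""Genotype records, zygosity coding, and genotype-table IO.

A genotype record holds one subject's unordered allele pair at every locus
of a panel, together with a cohort label and optional survival information.
Two codings of a locus are supported:

* three-state zygosity: ``a`` (homozygous major), ``ab`` (heterozygous),
  ``b`` (homozygous minor);
* two-state dominant: ``a`` if homozygous major, otherwise ``b`` — one or
  two copies of the minor allele are treated identically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .loci import LocusSpec, validate_loci

__all__ = [
    "COHORTS",
    "GenotypeRecord",
    "zygosity_state",
    "dominant_state",
    "read_genotype_table",
    "write_genotype_table",
    "read_vcf",
]

COHORTS = ("case", "control", "unknown")

#: States of the three-state (zygosity) coding, in canonical order a < ab < b.
THREE_STATES = ("a", "ab", "b")
#: States of the two-state (dominant) coding.
TWO_STATES = ("a", "b")


@dataclass(frozen=True)
class GenotypeRecord:
    """One subject's multilocus genotype.

    ``genotypes`` maps locus name to the unordered allele pair; pair order
    is preserved as read but never meaningful.
    """

    sample_id: str
    cohort: str
    genotypes: dict[str, tuple[str, str]]
    survival_days: float | None = None
    event: bool | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(
                f"sample {self.sample_id!r}: cohort {self.cohort!r} "
                f"not one of {COHORTS}"
            )
        if self.survival_days is not None and self.survival_days < 0:
            raise ValueError(
                f"sample {self.sample_id!r}: negative survival_days"
            )

    def validate(self, loci: Sequence[LocusSpec]) -> "GenotypeRecord":
        """Check every panel locus is present with alleles from its pair."""
        for locus in loci:
            pair = self.genotypes.get(locus.name)
            if pair is None:
                raise ValueError(
                    f"sample {self.sample_id!r}: missing genotype for locus "
                    f"{locus.name!r}"
                )
            for allele in pair:
                if allele not in locus.alleles:
                    raise ValueError(
                        f"sample {self.sample_id!r}, locus {locus.name!r}: "
                        f"allele {allele!r} is neither major "
                        f"({locus.major_allele!r}) nor minor "
                        f"({locus.minor_allele!r})"
                    )
        return self


def zygosity_state(record: GenotypeRecord, locus: LocusSpec) -> str:
    """Three-state coding of one locus: ``a``, ``ab`` or ``b``.

    Symmetric in the order of the allele pair.
    """
    x, y = record.genotypes[locus.name]
    n_minor = (x == locus.minor_allele) + (y == locus.minor_allele)
    return THREE_STATES[n_minor]


def dominant_state(record: GenotypeRecord, locus: LocusSpec) -> str:
    """Two-state dominant coding: ``b`` iff at least one minor allele."""
    return "a" if zygosity_state(record, locus) == "a" else "b"


# ---------------------------------------------------------------------------
# delimited-table IO

_META_COLUMNS = ("sample_id", "cohort", "survival_days", "event")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_genotype_table(
    path: str | Path,
    loci: Sequence[LocusSpec],
    *,
    drop_incomplete: bool = False,
) -> list[GenotypeRecord]:
    """Read subject genotypes from a delimited text table.

    The header must contain ``sample_id``, ``cohort``, optionally
    ``survival_days`` and ``event`` (0/1), and one column per panel locus
    holding ``X/Y`` allele pairs. Comma and tab delimiters are autodetected.
    Rows with missing genotypes raise unless ``drop_incomplete`` is set.
    """
    loci = validate_loci(loci)
    text = Path(path).read_text()
    delimiter = _sniff_delimiter(text.splitlines()[0])
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    header = reader.fieldnames or []
    for required in ("sample_id", "cohort"):
        if required not in header:
            raise ValueError(f"{path}: missing required column {required!r}")
    for locus in loci:
        if locus.name not in header:
            raise ValueError(f"{path}: missing locus column {locus.name!r}")

    records: list[GenotypeRecord] = []
    seen: set[str] = set()
    for lineno, row in enumerate(reader, start=2):
        sample_id = (row["sample_id"] or "").strip()
        if not sample_id:
            raise ValueError(f"{path}:{lineno}: empty sample_id")
        if sample_id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate sample_id {sample_id!r}")
        seen.add(sample_id)

        genotypes: dict[str, tuple[str, str]] = {}
        incomplete = False
        for locus in loci:
            cell = (row.get(locus.name) or "").strip()
            if not cell or cell.upper() in ("NA", "./."):
                incomplete = True
                if not drop_incomplete:
                    raise ValueError(
                        f"{path}:{lineno}: sample {sample_id!r} has no genotype "
                        f"for locus {locus.name!r}"
                    )
                continue
            alleles = cell.upper().split("/")
            if len(alleles) != 2:
                raise ValueError(
                    f"{path}:{lineno}: malformed genotype {cell!r} at "
                    f"{locus.name!r} (expected 'X/Y')"
                )
            genotypes[locus.name] = (alleles[0], alleles[1])
        if incomplete:
            continue

        survival = (row.get("survival_days") or "").strip()
        event = (row.get("event") or "").strip()
        record = GenotypeRecord(
            sample_id=sample_id,
            cohort=(row["cohort"] or "unknown").strip().lower(),
            genotypes=genotypes,
            survival_days=float(survival) if survival else None,
            event=bool(int(event)) if event else None,
        )
        records.append(record.validate(loci))
    return records


def write_genotype_table(
    records: Iterable[GenotypeRecord],
    path: str | Path,
    loci: Sequence[LocusSpec],
    *,
    delimiter: str = ",",
) -> None:
    """Write records in the format :func:`read_genotype_table` reads."""
    loci = validate_loci(loci)
    records = list(records)
    has_survival = any(r.survival_days is not None for r in records)
    header = ["sample_id", "cohort"]
    if has_survival:
        header += ["survival_days", "event"]
    header += [l.name for l in loci]

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(header)
        for r in records:
            row: list[str] = [r.sample_id, r.cohort]
            if has_survival:
                row.append("" if r.survival_days is None else f"{r.survival_days:g}")
                row.append("" if r.event is None else str(int(r.event)))
            row += ["/".join(r.genotypes[l.name]) for l in loci]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# optional VCF input

def read_vcf(
    path: str | Path,
    loci: Sequence[LocusSpec],
    *,
    cohort: str = "unknown",
) -> list[GenotypeRecord]:
    """Read genotypes from a VCF, matching loci by rsid in the ID column.

    Phased and unphased GT separators are both accepted; phase is discarded.
    Requires pysam. All samples get the supplied cohort label.
    """
    import pysam  # deferred: optional dependency

    loci = validate_loci(loci)
    by_rsid = {l.rsid: l for l in loci}
    calls: dict[str, dict[str, tuple[str, str]]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for sample in samples:
            calls[sample] = {}
        for rec in vcf.fetch():
            locus = by_rsid.get(rec.id or "")
            if locus is None:
                continue
            for sample in samples:
                alleles = rec.samples[sample].alleles
                if alleles is None or any(a is None for a in alleles):
                    raise ValueError(
                        f"{path}: sample {sample!r} has a missing call at "
                        f"{rec.id}"
                    )
                if len(alleles) != 2:
                    raise ValueError(
                        f"{path}: sample {sample!r} at {rec.id}: expected a "
                        f"diploid call, got {alleles!r}"
                    )
                calls[sample][locus.name] = (alleles[0], alleles[1])
    records = [
        GenotypeRecord(sample_id=s, cohort=cohort, genotypes=g).validate(loci)
        for s, g in calls.items()
    ]
    return records
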