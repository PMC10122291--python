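"""ABO diplotype inference from tag-polymorphism dosages.

Each of the five common ABO haplotypes is marked by one tag allele:
rs8176719-delG for O1, rs41302905-T for O2, rs2519093-T for A1,
rs1053878-A for A2 and rs8176743-T for B.  With hard (best-guess integer)
dosages at the five tags, a subject's pair of haplotypes is determined
without ambiguity exactly when the dosages sum to 2: a dosage-2 site means
homozygosity, two dosage-1 sites a heterozygous pair.  Any other total
leaves the diplotype unresolved.

Association coding is additive with O1 as reference: counts of the A1,
A2, B and O2 haplotypes (each 0-2, summing with the implicit O1 count
to 2).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import ABO_NON_REFERENCE, SubjectRecord

logger = logging.getLogger(__name__)

HAPLOTYPES = ("O1", "O2", "A1", "A2", "B")

#: tag polymorphism column name for each haplotype
TAG_SNPS = {
    "O1": "rs8176719_delG",
    "O2": "rs41302905_T",
    "A1": "rs2519093_T",
    "A2": "rs1053878_A",
    "B": "rs8176743_T",
}


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of ABO haplotype labels, or unresolved."""

    haplotypes: tuple[str, str] | None

    @property
    def resolved(self) -> bool:
        return self.haplotypes is not None

    def __str__(self) -> str:
        if self.haplotypes is None:
            return "UNRESOLVED"
        return "/".join(self.haplotypes)


UNRESOLVED = Diplotype(None)


def _check_dosage(hap: str, value) -> int:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"dosage for {hap} is not numeric: {value!r}") from None
    if not v.is_integer():
        raise ValueError(
            f"fractional dosage {value!r} for {hap}: round best-guess genotypes "
            "explicitly before inference"
        )
    v = int(v)
    if v not in (0, 1, 2):
        raise ValueError(f"dosage for {hap} outside 0-2: {value!r}")
    return v


def infer_diplotype(dosages: Mapping[str, int]) -> Diplotype:
    """Infer the haplotype pair from tag dosages.

    Resolves iff the five dosages total exactly 2; otherwise returns
    ``UNRESOLVED`` (the subject's blood group cannot be determined
    unambiguously).
    """
    unknown = set(dosages) - set(HAPLOTYPES)
    if unknown:
        raise ValueError(f"unknown haplotype labels: {sorted(unknown)}")
    counts = {h: _check_dosage(h, dosages.get(h, 0)) for h in HAPLOTYPES}
    if sum(counts.values()) != 2:
        return UNRESOLVED
    pair = [h for h in HAPLOTYPES for _ in range(counts[h])]
    return Diplotype((pair[0], pair[1]))


def additive_coding(dip: Diplotype) -> dict[str, int]:
    """Counts of A1, A2, B and O2 haplotypes (O1 is the reference level)."""
    if not dip.resolved:
        raise ValueError("cannot code an unresolved diplotype")
    return {h: dip.haplotypes.count(h) for h in ABO_NON_REFERENCE}


# ---------------------------------------------------------------------------
# Genotype files and cohort attachment

def read_genotypes(path) -> pd.DataFrame:
    """Read a genotype dosage CSV (subject_id plus the five tag columns)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("subject_id", *TAG_SNPS.values()) if c not in df.columns]
    if missing:
        raise ValueError(f"genotype file missing columns: {missing}")
    return df.set_index(df["subject_id"].astype(str))


@dataclass
class AboAssignment:
    n_resolved: int
    n_unresolved: int
    n_missing: int
    unresolved_ids: list[str]


def assign_diplotypes(
    records: Sequence[SubjectRecord], genotypes: pd.DataFrame
) -> AboAssignment:
    """Attach additive ABO coding to each record from its tag dosages.

    Unresolved subjects keep ``abo_dosages = None`` and their count is
    logged; association fits exclude them (with their own logged count).
    """
    n_res = n_unres = n_miss = 0
    unresolved_ids: list[str] = []
    for r in records:
        if r.subject_id not in genotypes.index:
            r.abo_dosages = None
            n_miss += 1
            continue
        row = genotypes.loc[r.subject_id]
        dip = infer_diplotype({h: row[c] for h, c in TAG_SNPS.items()})
        if dip.resolved:
            r.abo_dosages = additive_coding(dip)
            n_res += 1
        else:
            r.abo_dosages = None
            n_unres += 1
            unresolved_ids.append(r.subject_id)
    if n_unres or n_miss:
        logger.info(
            "ABO assignment: %d resolved, %d unresolved, %d without genotypes",
            n_res, n_unres, n_miss,
        )
    return AboAssignment(n_res, n_unres, n_miss, unresolved_ids)


def dosage_frame(diplotypes: Mapping[str, Diplotype]) -> pd.DataFrame:
    """Tag-dosage table (one row per subject) consistent with the given
    diplotypes; inverse of :func:`infer_diplotype` row-wise."""
    rows = []
    for sid, dip in diplotypes.items():
        if not dip.resolved:
            raise ValueError(f"cannot emit dosages for unresolved diplotype ({sid})")
        row = {"subject_id": sid}
        for h in HAPLOTYPES:
            row[TAG_SNPS[h]] = dip.haplotypes.count(h)
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", *TAG_SNPS.values()])
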