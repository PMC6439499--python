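"""Readers and writers for genotype, map, and haul tables.

Supported formats: Genepop with 4-digit two-allele codes ("0000" is
missing), a wide CSV dosage layout (rows = individuals, columns = loci,
cells 0/1/2/NA), a locus-map CSV (locus_id, linkage_group, cM), and the
haul observation CSV consumed by the mixing models.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mixing import HaulObservation
from .popgen import MISSING, GenotypeMatrix, LocusInfo

__all__ = [
    "read_genepop",
    "write_genepop",
    "read_dosage_csv",
    "write_dosage_csv",
    "read_locus_map",
    "write_locus_map",
    "read_haul_table",
    "write_haul_table",
]


class GenepopParseError(ValueError):
    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def write_genepop(gm: GenotypeMatrix, path: str | Path, title: str = "gsikit export", pops: Sequence[str] | None = None) -> None:
    """Write a genotype matrix using '01' (ref) / '02' (alt) codes.

    ``pops`` optionally gives a population label per individual; runs of
    the same label become POP sections (default: a single section)."""
    code = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
    lines = [title]
    lines.extend(gm.locus_ids)
    prev = object()
    labels = pops if pops is not None else ["pop"] * gm.n_individuals
    for i, ind in enumerate(gm.individuals):
        if labels[i] != prev:
            lines.append("POP")
            prev = labels[i]
        genos = " ".join(code[int(d)] for d in gm.dosage[i])
        lines.append(f"{ind} ,  {genos}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(
    path: str | Path, loci: Sequence[LocusInfo] | None = None
) -> tuple[GenotypeMatrix, list[str]]:
    """Parse a Genepop file into (GenotypeMatrix, per-individual pop label).

    Allele codes map to dosage via a per-locus coding table: with
    reference loci supplied, orientation follows their allele codes;
    otherwise the numerically smaller observed code is the reference
    allele, so files sharing a locus list decode consistently."""
    raw = Path(path).read_text().splitlines()
    if not raw:
        raise GenepopParseError("empty file", 1)
    # locus names: lines after the title until the first POP, possibly
    # comma-separated on a single line
    locus_names: list[str] = []
    i = 1
    while i < len(raw) and raw[i].strip().upper() != "POP":
        chunk = [s.strip() for s in raw[i].split(",") if s.strip()]
        locus_names.extend(chunk)
        i += 1
    if i == len(raw):
        raise GenepopParseError("no POP line found", len(raw))
    if len(set(locus_names)) != len(locus_names):
        raise GenepopParseError("duplicated locus names", i)
    L = len(locus_names)

    individuals: list[str] = []
    pops: list[str] = []
    rows: list[list[str]] = []
    pop_counter = 0
    for ln in range(i, len(raw)):
        line = raw[ln].strip()
        if not line:
            continue
        if line.upper() == "POP":
            pop_counter += 1
            continue
        if "," not in line:
            raise GenepopParseError("expected 'id , genotypes'", ln + 1)
        ind, genos = line.split(",", 1)
        codes = genos.split()
        if len(codes) != L:
            raise GenepopParseError(
                f"expected {L} genotypes, found {len(codes)}", ln + 1
            )
        for c in codes:
            if len(c) != 4 or not c.isdigit():
                raise GenepopParseError(f"invalid genotype code {c!r}", ln + 1)
        individuals.append(ind.strip())
        pops.append(f"pop{pop_counter}")
        rows.append(codes)

    if not individuals:
        raise GenepopParseError("no individuals found", len(raw))

    # per-locus allele coding: reference loci with 2-digit allele codes
    # pin the ref/alt orientation; otherwise the numerically smaller
    # observed code is the reference allele
    allele_codes: list[tuple[str, str]] = []
    ref_codes: list[tuple[str, str] | None] = [None] * L
    if loci is not None:
        if [l.locus_id for l in loci] != locus_names:
            raise ValueError("reference loci do not match file locus names")
        for j, l in enumerate(loci):
            a, b = l.alleles
            if len(a) == 2 and len(b) == 2 and a.isdigit() and b.isdigit():
                ref_codes[j] = (a, b)
    for j in range(L):
        seen = set()
        for r in rows:
            c = r[j]
            if c == "0000":
                continue
            seen.update((c[:2], c[2:]))
        seen.discard("00")
        if len(seen) > 2:
            raise ValueError(
                f"locus {locus_names[j]} has more than two alleles: {sorted(seen)}"
            )
        if ref_codes[j] is not None:
            unknown = seen - set(ref_codes[j])
            if unknown:
                raise ValueError(
                    f"locus {locus_names[j]}: allele codes {sorted(unknown)} not in "
                    f"reference coding {ref_codes[j]}"
                )
            allele_codes.append(ref_codes[j])
            continue
        ordered = sorted(seen)
        if len(ordered) == 0:
            ordered = ["01", "02"]
        elif len(ordered) == 1:
            other = "01" if ordered[0] != "01" else "02"
            ordered = sorted([ordered[0], other])
        allele_codes.append((ordered[0], ordered[1]))

    dosage = np.full((len(individuals), L), MISSING, dtype=np.int8)
    for ii, r in enumerate(rows):
        for j, c in enumerate(r):
            if c == "0000":
                continue
            a1, a2 = c[:2], c[2:]
            if "00" in (a1, a2):
                raise ValueError(
                    f"half-missing genotype {c!r} for {individuals[ii]} at {locus_names[j]}"
                )
            ref, alt = allele_codes[j]
            dosage[ii, j] = int(a1 == alt) + int(a2 == alt)

    if loci is not None:
        out_loci = list(loci)
    else:
        out_loci = [
            LocusInfo(name, alleles=allele_codes[j]) for j, name in enumerate(locus_names)
        ]
    return GenotypeMatrix(individuals, out_loci, dosage), pops


def write_dosage_csv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        np.where(gm.dosage == MISSING, np.nan, gm.dosage),
        index=pd.Index(gm.individuals, name="individual_id"),
        columns=gm.locus_ids,
    )
    df.to_csv(path, float_format="%.0f")


def read_dosage_csv(path: str | Path, loci: Sequence[LocusInfo] | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy(dtype=float)
    bad = np.isfinite(vals) & ~np.isin(vals, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid dosage {vals[i, j]} for {df.index[i]} at {df.columns[j]}"
        )
    dosage = np.where(np.isfinite(vals), vals, MISSING).astype(np.int8)
    if loci is not None:
        if [l.locus_id for l in loci] != list(df.columns):
            raise ValueError("reference loci do not match CSV columns")
        out_loci = list(loci)
    else:
        out_loci = [LocusInfo(c) for c in df.columns]
    return GenotypeMatrix(list(df.index.astype(str)), out_loci, dosage)


def write_locus_map(loci: Sequence[LocusInfo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "linkage_group": [l.linkage_group for l in loci],
            "cM": [l.map_pos for l in loci],
        }
    ).to_csv(path, index=False)


def read_locus_map(path: str | Path) -> list[LocusInfo]:
    df = pd.read_csv(path)
    required = {"locus_id", "linkage_group", "cM"}
    if not required <= set(df.columns):
        raise ValueError(f"locus map must have columns {sorted(required)}")
    return [
        LocusInfo(str(r.locus_id), str(r.linkage_group), float(r.cM))
        for r in df.itertuples()
    ]


HAUL_COLUMNS = [
    "haul_id",
    "period_id",
    "utm_x",
    "area",
    "life_stage",
    "east_count",
    "n_fish",
    "salinity",
    "oxygen",
    "temperature",
]


def write_haul_table(hauls: Sequence[HaulObservation], path: str | Path) -> None:
    pd.DataFrame([vars(h) for h in hauls])[HAUL_COLUMNS].to_csv(path, index=False)


def read_haul_table(path: str | Path) -> list[HaulObservation]:
    df = pd.read_csv(path)
    missing = set(HAUL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"haul table missing columns {sorted(missing)}")
    return [
        HaulObservation(
            haul_id=str(r.haul_id),
            period_id=str(r.period_id),
            east_count=int(r.east_count),
            n_fish=int(r.n_fish),
            utm_x=float(r.utm_x),
            area=str(r.area),
            life_stage=str(r.life_stage),
            salinity=float(r.salinity),
            oxygen=float(r.oxygen),
            temperature=float(r.temperature),
        )
        for r in df.itertuples()
    ]
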