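"""Genotype and metadata input/output.

Core containers:

* :class:`GenotypeTable` — individuals x loci diploid allele-length calls
  (integer base pairs, 0 = missing), pairs stored sorted ascending.
* sample metadata — a :class:`pandas.DataFrame` with columns
  ``individual_id, amu_code, sex, age_class``.
* :class:`AmuRecord` — one management unit (census, area, centroid, region).

Supported formats: GenePop 4.x (2- and 3-digit codes read, 3-digit written)
and a CSV dialect with two columns per locus (``<locus>_1``, ``<locus>_2``).
Allele sizes are stored exactly as typed; binning is upstream of this
package.  Missing data are recorded, never imputed; individuals whose
missing fraction exceeds a configurable limit are dropped with a log entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_VALUES = {"M", "F", "unknown"}


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype files."""


class ValidationError(ValueError):
    """Raised when joined tables violate referential integrity."""


@dataclass
class GenotypeTable:
    """Diploid genotype calls for a set of individuals.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` with integer allele
    sizes in base pairs; 0 marks a missing call.  A call with either allele
    missing is treated as a missing pair.  Pairs are stored sorted ascending
    so that unordered genotypes compare deterministically.
    """

    individual_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individual_ids), len(self.locus_names), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_names)} loci"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            dupes = pd.Series(self.individual_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate individual ids: {dupes}")
        if (self.calls < 0).any():
            raise ValueError("allele sizes must be non-negative integers (0 = missing)")
        # normalise: partial missing -> fully missing; sort pairs ascending
        partial = (self.calls == 0).any(axis=2)
        self.calls[partial] = 0
        self.calls = np.sort(self.calls, axis=2)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing calls."""
        return (self.calls == 0).any(axis=2)

    def missing_fraction(self, per_individual: bool = False) -> np.ndarray | float:
        m = self.missing_mask()
        if per_individual:
            return m.mean(axis=1)
        return float(m.mean())

    def subset(self, individual_ids: Sequence[str]) -> "GenotypeTable":
        index = {iid: i for i, iid in enumerate(self.individual_ids)}
        missing = [iid for iid in individual_ids if iid not in index]
        if missing:
            raise ValidationError(f"unknown individual ids: {missing}")
        rows = [index[iid] for iid in individual_ids]
        return GenotypeTable(list(individual_ids), list(self.locus_names), self.calls[rows].copy())

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and self.locus_names == other.locus_names
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class LocusDef:
    """A microsatellite marker definition (name and allele-size window)."""

    name: str
    size_range: tuple[int, int]
    multiplex_group: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not lo < hi:
            raise ValueError(f"locus {self.name}: size range must satisfy min < max, got {self.size_range}")


@dataclass
class AmuRecord:
    """One administrative management unit (AMU).

    ``census_nc`` is the spring census estimate Nc; ``n_samples`` the number
    of genotyped individuals attributed to the unit.
    """

    code: str
    name: str
    area_km2: float
    census_nc: float
    n_samples: int = 0
    region: str | None = None
    centroid_lat: float = float("nan")
    centroid_lon: float = float("nan")
    isolated_flag: bool | None = None

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValueError(f"AMU {self.code}: area must be positive")
        if self.census_nc <= 0:
            raise ValueError(f"AMU {self.code}: census estimate must be positive")
        if np.isfinite(self.centroid_lat) and not -90 <= self.centroid_lat <= 90:
            raise ValueError(f"AMU {self.code}: latitude {self.centroid_lat} out of range")
        if np.isfinite(self.centroid_lon) and not -180 <= self.centroid_lon <= 180:
            raise ValueError(f"AMU {self.code}: longitude {self.centroid_lon} out of range")
        if self.n_samples < 0:
            raise ValueError(f"AMU {self.code}: n_samples must be non-negative")
        if self.n_samples > 2 * self.census_nc:
            raise ValueError(
                f"AMU {self.code}: n_samples={self.n_samples} exceeds twice the census estimate"
            )


def amus_to_frame(amus: Iterable[AmuRecord]) -> pd.DataFrame:
    rows = [
        {
            "code": a.code,
            "name": a.name,
            "region": a.region if a.region is not None else "",
            "area_km2": a.area_km2,
            "census_nc": a.census_nc,
            "n_samples": a.n_samples,
            "lat": a.centroid_lat,
            "lon": a.centroid_lon,
        }
        for a in amus
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def read_genepop(path: str | Path) -> tuple[GenotypeTable, pd.DataFrame]:
    """Read a GenePop 4.x file.

    Returns the genotype table and a provisional sample table
    (``individual_id``, ``amu_code``) in which each population block is
    labelled by its first individual id; callers typically replace these
    labels with real unit codes.

    Accepts 2- and 3-digit allele codes (``00``/``000`` = missing).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise GenotypeFormatError(f"{path}: not a GenePop file (fewer than 3 lines)")
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [s.strip() for s in lines[i].split(",") if s.strip()]
        locus_names.extend(chunk)
        i += 1
    if not locus_names or i == len(lines):
        raise GenotypeFormatError(f"{path}: no locus list / 'Pop' line found")

    ids: list[str] = []
    pops: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    width: int | None = None
    block_label = ""
    for line in lines[i:]:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            block_label = ""
            continue
        if "," not in stripped:
            raise GenotypeFormatError(f"{path}: data row without ',' separator: {stripped!r}")
        ind_id, geno_part = stripped.split(",", 1)
        ind_id = ind_id.strip()
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise GenotypeFormatError(
                f"{path}: individual {ind_id!r} has {len(tokens)} genotypes, expected {len(locus_names)}"
            )
        if not block_label:
            block_label = ind_id
        row: list[tuple[int, int]] = []
        for locus, tok in zip(locus_names, tokens):
            if len(tok) == 4:
                w = 2
            elif len(tok) == 6:
                w = 3
            else:
                raise GenotypeFormatError(
                    f"{path}: genotype {tok!r} at locus {locus} of {ind_id!r} has unsupported code width"
                )
            if width is None:
                width = w
            elif width != w:
                raise GenotypeFormatError(f"{path}: mixed 2- and 3-digit allele codes")
            try:
                a, b = int(tok[:w]), int(tok[w:])
            except ValueError as exc:
                raise GenotypeFormatError(f"{path}: non-numeric genotype {tok!r} for {ind_id!r}") from exc
            row.append((a, b))
        ids.append(ind_id)
        pops.append(block_label)
        calls.append(row)
    table = GenotypeTable(ids, locus_names, np.array(calls, dtype=np.int64))
    samples = pd.DataFrame({"individual_id": ids, "amu_code": pops})
    return table, samples


def write_genepop(
    table: GenotypeTable,
    path: str | Path,
    grouping: Mapping[str, str] | pd.DataFrame | None = None,
    title: str = "amupopgen export",
) -> Path:
    """Write a GenePop file with 3-digit allele codes (000 = missing).

    ``grouping`` maps individual ids to population codes; omitted, a single
    population block is written.
    """
    path = Path(path)
    if (table.calls > 999).any():
        raise GenotypeFormatError("allele sizes above 999 bp cannot be written as 3-digit codes")
    if isinstance(grouping, pd.DataFrame):
        grouping = dict(zip(grouping["individual_id"], grouping["amu_code"]))
    if grouping is None:
        blocks: dict[str, list[int]] = {"pop1": list(range(table.n_individuals))}
    else:
        blocks = {}
        for i, iid in enumerate(table.individual_ids):
            if iid not in grouping:
                raise ValidationError(f"individual {iid!r} missing from grouping")
            blocks.setdefault(grouping[iid], []).append(i)
    out = [title]
    out.extend(table.locus_names)
    for code in blocks:
        out.append("Pop")
        for i in blocks[code]:
            geno = " ".join(f"{a:03d}{b:03d}" for a, b in table.calls[i])
            out.append(f"{table.individual_ids[i]} , {geno}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _genotypes_from_frame(df: pd.DataFrame) -> GenotypeTable:
    cols = [c for c in df.columns if c != "individual_id"]
    loci: list[str] = []
    for c in cols:
        if c.endswith("_1"):
            locus = c[:-2]
            if f"{locus}_2" not in df.columns:
                raise GenotypeFormatError(f"genotype csv: column {locus}_2 missing")
            loci.append(locus)
    if not loci:
        raise GenotypeFormatError("genotype csv: no '<locus>_1'/'<locus>_2' column pairs found")
    calls = np.zeros((len(df), len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        for k in (1, 2):
            col = pd.to_numeric(df[f"{locus}_{k}"], errors="raise").fillna(0)
            calls[:, j, k - 1] = col.astype(np.int64).to_numpy()
    return GenotypeTable(df["individual_id"].astype(str).tolist(), loci, calls)


def read_tables(
    genotype_csv: str | Path,
    sample_csv: str | Path,
    amu_csv: str | Path,
    max_missing_per_individual: float = 0.2,
    amu_aliases: Mapping[str, str] | None = None,
) -> tuple[GenotypeTable, pd.DataFrame, list[AmuRecord]]:
    """Read and join the project's CSV triplet.

    ``amu_aliases`` folds tiny sampling units into neighbours (e.g. a unit
    with a handful of samples analysed with its neighbour); aliasing is
    applied to the sample table before validation and is always explicit,
    never automatic.  Individuals whose missing-call fraction exceeds
    ``max_missing_per_individual`` are dropped and logged.
    """
    gdf = pd.read_csv(genotype_csv)
    table = _genotypes_from_frame(gdf)
    samples = pd.read_csv(sample_csv, dtype=str).fillna("")
    required = {"individual_id", "amu_code"}
    if not required <= set(samples.columns):
        raise ValidationError(f"sample csv must contain columns {sorted(required)}")
    if "sex" not in samples.columns:
        samples["sex"] = "unknown"
    samples.loc[~samples["sex"].isin(SEX_VALUES), "sex"] = "unknown"
    if "age_class" not in samples.columns:
        samples["age_class"] = ""
    if amu_aliases:
        samples["amu_code"] = samples["amu_code"].replace(dict(amu_aliases))
    if samples["individual_id"].duplicated().any():
        dupes = sorted(samples.loc[samples["individual_id"].duplicated(), "individual_id"].unique())
        raise ValidationError(f"duplicate individual ids in sample table: {dupes}")

    known = set(samples["individual_id"])
    orphans = [iid for iid in table.individual_ids if iid not in known]
    if orphans:
        raise ValidationError(f"individuals in genotype file absent from sample file: {orphans}")

    adf = pd.read_csv(amu_csv)
    codes = set(adf["code"].astype(str))
    bad = sorted(set(samples["amu_code"]) - codes)
    if bad:
        raise ValidationError(f"sample rows reference undefined AMU codes: {bad}")

    # drop high-missingness individuals (recorded, never imputed)
    frac = table.missing_fraction(per_individual=True)
    keep = frac <= max_missing_per_individual
    if not keep.all():
        dropped = [iid for iid, k in zip(table.individual_ids, keep) if not k]
        logger.warning(
            "dropping %d individual(s) with more than %.0f%% missing calls: %s",
            len(dropped), 100 * max_missing_per_individual, dropped,
        )
        table = table.subset([iid for iid, k in zip(table.individual_ids, keep) if k])
        samples = samples[samples["individual_id"].isin(table.individual_ids)].reset_index(drop=True)

    counts = samples["amu_code"].value_counts()
    amus: list[AmuRecord] = []
    for _, row in adf.iterrows():
        code = str(row["code"])
        n = int(counts.get(code, 0))
        if "n_samples" in adf.columns and not pd.isna(row["n_samples"]):
            stated = int(row["n_samples"])
            if stated != n and keep.all():
                raise ValidationError(
                    f"AMU {code}: stated n_samples={stated} does not match sample table count {n}"
                )
        amus.append(
            AmuRecord(
                code=code,
                name=str(row.get("name", code)),
                region=(str(row["region"]) if "region" in adf.columns and not pd.isna(row["region"]) else None),
                area_km2=float(row["area_km2"]),
                census_nc=float(row["census_nc"]),
                n_samples=n,
                centroid_lat=float(row["lat"]),
                centroid_lon=float(row["lon"]),
            )
        )
    return table, samples, amus


def write_tables(
    table: GenotypeTable,
    samples: pd.DataFrame,
    amus: Iterable[AmuRecord],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write genotypes.csv, samples.csv and amus.csv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data: dict[str, object] = {"individual_id": table.individual_ids}
    for j, locus in enumerate(table.locus_names):
        for k in (1, 2):
            col = table.calls[:, j, k - 1].astype(object)
            data[f"{locus}_{k}"] = [v if v else "" for v in col]
    paths = {
        "genotypes": out_dir / "genotypes.csv",
        "samples": out_dir / "samples.csv",
        "amus": out_dir / "amus.csv",
    }
    pd.DataFrame(data).to_csv(paths["genotypes"], index=False)
    samples.to_csv(paths["samples"], index=False)
    amus_to_frame(amus).to_csv(paths["amus"], index=False)
    return paths


def write_results(df: pd.DataFrame, path: str | Path, float_format: str = "%.6f") -> Path:
    """Write a result table as UTF-8 TSV with fixed float precision.

    Column order is preserved as given, so repeated runs diff cleanly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format, encoding="utf-8")
    return path
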