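"""Reading, validating and subsetting diploid microsatellite genotype data.

The central container is :class:`GenotypeMatrix`: individuals x loci diploid
allele-size calls (fragment sizes in base pairs), optional planar sample
coordinates in km, and optional per-individual annotations.  Alleles are
stored sorted within each genotype (unordered pairs) and missing data uses a
dedicated sentinel, never 0, so GenePop "00"/"000" codes cannot collide with
real calls.

Supported formats: GenePop (.gen, 2- or 3-digit coding) and a flat
one-row-per-individual table (CSV or XLSX) with two columns per locus, the
common supplementary-table dialect of wildlife microsatellite studies.
Coordinates are taken as already projected planar km (x = east, y = north);
no geodesy is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call.  Deliberately not 0.
MISSING = -9


class GenotypeParseError(ValueError):
    """Malformed genotype input; message names the offending line/cell."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus.

    Parameters
    ----------
    name
        Unique locus name within a panel.
    repeat_motif_length
        Base pairs per repeat unit (1-4 for mono- to tetranucleotide
        repeats).  Needed only by repeat-unit statistics such as the
        Garza-Williamson index.
    """

    name: str
    repeat_motif_length: int = 2

    def __post_init__(self) -> None:
        if self.repeat_motif_length < 1:
            raise ValueError(f"locus {self.name}: motif length must be >= 1")


@dataclass
class GenotypeMatrix:
    """Diploid multilocus genotypes with sample metadata.

    ``calls`` has shape (n, L, 2), integer allele sizes in base pairs with
    :data:`MISSING` for no-calls; each genotype is stored sorted ascending
    (unordered pair).  Either both alleles of a genotype are missing or
    neither.
    """

    individual_ids: list[str]
    loci: list[Locus]
    calls: np.ndarray
    coordinates: np.ndarray | None = None
    group_labels: list[str] | None = None
    sex: list[str] | None = None
    age: list[float] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        # normalise to sorted unordered pairs; missing sorts as a pair
        half_missing = (self.calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            i, l = np.argwhere(half_missing)[0]
            raise GenotypeParseError(
                f"individual {self.individual_ids[i]!r} locus "
                f"{self.loci[l].name!r}: half-missing genotype"
            )
        self.calls = np.sort(self.calls, axis=2)
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.validate()

    # -- basic shape -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean mask of missing genotypes."""
        return self.calls[:, :, 0] == MISSING

    def validate(self) -> None:
        n, L = self.n, self.n_loci
        if self.calls.shape != (n, L, 2):
            raise GenotypeParseError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{n} individuals x {L} loci"
            )
        if len(set(self.individual_ids)) != n:
            raise GenotypeParseError("duplicate individual ids")
        if len(set(self.locus_names)) != L:
            raise GenotypeParseError("duplicate locus names")
        bad = (self.calls <= 0) & (self.calls != MISSING)
        if bad.any():
            i, l, _ = np.argwhere(bad)[0]
            raise GenotypeParseError(
                f"non-positive allele size for {self.individual_ids[i]!r} "
                f"at {self.loci[l].name!r}"
            )
        if self.coordinates is not None and self.coordinates.shape != (n, 2):
            raise GenotypeParseError("coordinates must be n x 2 (km)")
        for name, ann in (
            ("group_labels", self.group_labels),
            ("sex", self.sex),
            ("age", self.age),
        ):
            if ann is not None and len(ann) != n:
                raise GenotypeParseError(f"{name} length != n individuals")

    # -- subsetting ------------------------------------------------------
    def subset_individuals(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        take = lambda seq: [seq[i] for i in idx] if seq is not None else None
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
            coordinates=None if self.coordinates is None else self.coordinates[idx].copy(),
            group_labels=take(self.group_labels),
            sex=take(self.sex),
            age=take(self.age),
        )

    def subset_by_ids(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {iid: i for i, iid in enumerate(self.individual_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"unknown individual ids: {missing}")
        return self.subset_individuals([pos[i] for i in ids])

    def with_groups(self, labels: Sequence[str]) -> "GenotypeMatrix":
        gm = self.subset_individuals(np.arange(self.n))
        gm.group_labels = list(labels)
        gm.validate()
        return gm

    # -- allele frequencies ---------------------------------------------
    def allele_frequencies(self) -> "AlleleFrequencyTable":
        return AlleleFrequencyTable.from_matrix(self)


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies and gene-copy counts.

    ``freqs[locus_name]`` maps allele size -> frequency; ``n_copies`` is
    2 x (non-missing individuals) per locus.
    """

    locus_names: list[str]
    freqs: dict[str, dict[int, float]]
    n_copies: dict[str, int]

    @classmethod
    def from_matrix(cls, gm: GenotypeMatrix) -> "AlleleFrequencyTable":
        freqs: dict[str, dict[int, float]] = {}
        n_copies: dict[str, int] = {}
        for l, loc in enumerate(gm.loci):
            col = gm.calls[:, l, :].ravel()
            col = col[col != MISSING]
            n_copies[loc.name] = col.size
            if col.size == 0:
                freqs[loc.name] = {}
                continue
            vals, counts = np.unique(col, return_counts=True)
            freqs[loc.name] = {int(v): c / col.size for v, c in zip(vals, counts)}
        return cls(gm.locus_names, freqs, n_copies)

    def counts(self, locus: str) -> dict[int, float]:
        """Allele copy counts (frequency x gene copies)."""
        n = self.n_copies[locus]
        return {a: f * n for a, f in self.freqs[locus].items()}


# ---------------------------------------------------------------------------
# GenePop format
# ---------------------------------------------------------------------------

def read_genepop(path: str | Path, allele_offset: int = 0,
                 motif_lengths: Mapping[str, int] | None = None) -> GenotypeMatrix:
    """Read a GenePop file (2- or 3-digit allele coding).

    POP blocks become ``group_labels`` ("POP1", "POP2", ...).  Codes
    "00"/"000" decode to missing.  ``allele_offset`` is added to every
    decoded code, for panels whose GenePop export dropped a leading digit
    (e.g. 2-digit code "01" for a 101 bp fragment with offset 100).
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    # line 1: title; then locus names until first POP
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = [s.strip() for s in lines[i].split(",") if s.strip()]
        if not chunk:
            raise GenotypeParseError(f"{path}: line {i + 1}: empty locus line")
        locus_names.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenotypeParseError(f"{path}: no POP block found")
    L = len(locus_names)
    ids: list[str] = []
    groups: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop = 0
    digit_width: int | None = None
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.upper() == "POP":
            pop += 1
            continue
        if "," not in line:
            raise GenotypeParseError(
                f"{path}: line {i}: expected 'id , genotypes' row"
            )
        ident, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != L:
            raise GenotypeParseError(
                f"{path}: line {i}: {len(tokens)} genotypes for {L} loci"
            )
        row = []
        for tok in tokens:
            if not re.fullmatch(r"\d+", tok) or len(tok) % 2 != 0:
                raise GenotypeParseError(f"{path}: line {i}: bad genotype {tok!r}")
            w = len(tok) // 2
            if w not in (2, 3):
                raise GenotypeParseError(
                    f"{path}: line {i}: allele coding must be 2 or 3 digits"
                )
            if digit_width is None:
                digit_width = w
            elif w != digit_width:
                raise GenotypeParseError(
                    f"{path}: line {i}: mixed digit widths ({w} vs {digit_width})"
                )
            a, b = int(tok[:w]), int(tok[w:])
            row.append(
                (MISSING if a == 0 else a + allele_offset,
                 MISSING if b == 0 else b + allele_offset)
            )
        # tolerate one-sided 0 codes by treating the pair as missing
        row = [(MISSING, MISSING) if MISSING in pair else pair for pair in row]
        ids.append(ident.strip())
        groups.append(f"POP{pop}")
        rows.append(row)
    if not rows:
        raise GenotypeParseError(f"{path}: no individuals")
    motif_lengths = motif_lengths or {}
    loci = [Locus(nm, motif_lengths.get(nm, 2)) for nm in locus_names]
    return GenotypeMatrix(ids, loci, np.array(rows), group_labels=groups)


def write_genepop(gm: GenotypeMatrix, path: str | Path, title: str = "msatland export",
                  digits: int = 3, allele_offset: int = 0) -> None:
    """Write GenePop; one POP block per distinct group label (file order)."""
    fmt = f"%0{digits}d"
    groups = gm.group_labels or ["POP1"] * gm.n
    out = [title]
    out.extend(gm.locus_names)
    current = None
    for i in range(gm.n):
        if groups[i] != current:
            out.append("POP")
            current = groups[i]
        cells = []
        for l in range(gm.n_loci):
            a, b = gm.calls[i, l]
            code = lambda x: fmt % 0 if x == MISSING else fmt % (x - allele_offset)
            cells.append(code(a) + code(b))
        out.append(f"{gm.individual_ids[i]} , " + " ".join(cells))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Flat sample table (supplementary-table dialect)
# ---------------------------------------------------------------------------

@dataclass
class TableLayout:
    """Column mapping for the flat one-row-per-individual table.

    ``locus_columns`` maps locus name -> (allele-1 column, allele-2 column).
    Coordinates may come either from ``x_col``/``y_col`` (planar km, already
    projected) or from ``district_col`` plus a ``district_coordinates``
    lookup (district name -> (x, y) km).
    """

    id_col: str = "id"
    locus_columns: dict[str, tuple[str, str]] = field(default_factory=dict)
    x_col: str | None = None
    y_col: str | None = None
    district_col: str | None = None
    district_coordinates: dict[str, tuple[float, float]] | None = None
    sex_col: str | None = None
    age_col: str | None = None
    group_col: str | None = None
    motif_lengths: dict[str, int] = field(default_factory=dict)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_sample_table(path: str | Path, layout: TableLayout) -> GenotypeMatrix:
    """Read the flat per-individual table according to ``layout``.

    Empty allele pairs become missing genotypes; a non-integer allele cell
    raises :class:`GenotypeParseError` naming the row and column.
    """
    df = _read_table(path)
    needed = [layout.id_col] + [c for pair in layout.locus_columns.values() for c in pair]
    for c in (layout.x_col, layout.y_col, layout.district_col,
              layout.sex_col, layout.age_col, layout.group_col):
        if c is not None:
            needed.append(c)
    absent = [c for c in needed if c not in df.columns]
    if absent:
        raise GenotypeParseError(f"{path}: missing mapped columns {absent}")

    ids = [str(v) for v in df[layout.id_col]]
    n = len(ids)
    loci = [Locus(nm, layout.motif_lengths.get(nm, 2)) for nm in layout.locus_columns]
    calls = np.full((n, len(loci), 2), MISSING, dtype=np.int64)
    for l, (nm, (ca, cb)) in enumerate(layout.locus_columns.items()):
        for i in range(n):
            va, vb = df[ca].iloc[i], df[cb].iloc[i]
            if (pd.isna(va) or va == "") and (pd.isna(vb) or vb == ""):
                continue
            try:
                a, b = int(va), int(vb)
            except (TypeError, ValueError):
                raise GenotypeParseError(
                    f"{path}: row {i + 2}, locus {nm} ({ca}/{cb}): "
                    f"non-integer allele cell {va!r}/{vb!r}"
                ) from None
            calls[i, l] = (a, b)

    coords = None
    if layout.x_col and layout.y_col:
        coords = df[[layout.x_col, layout.y_col]].to_numpy(dtype=float)
    elif layout.district_col:
        if layout.district_coordinates is None:
            raise GenotypeParseError(
                "district_col given without a district_coordinates lookup"
            )
        try:
            coords = np.array(
                [layout.district_coordinates[str(d)] for d in df[layout.district_col]],
                dtype=float,
            )
        except KeyError as e:
            raise GenotypeParseError(f"{path}: unknown district {e.args[0]!r}") from None

    opt = lambda col, cast: None if col is None else [cast(v) for v in df[col]]
    return GenotypeMatrix(
        ids, loci, calls,
        coordinates=coords,
        group_labels=opt(layout.group_col, str),
        sex=opt(layout.sex_col, str),
        age=None if layout.age_col is None else
            [float(v) if not pd.isna(v) else np.nan for v in df[layout.age_col]],
    )


def write_sample_table(gm: GenotypeMatrix, path: str | Path) -> TableLayout:
    """Write the flat-table dialect (CSV, '.' decimal); returns the layout
    that reads it back.  Round-trips calls, ids and coordinates bit-exactly.
    """
    data: dict[str, list] = {"id": gm.individual_ids}
    locus_columns = {}
    for l, loc in enumerate(gm.loci):
        ca, cb = f"{loc.name}_a", f"{loc.name}_b"
        locus_columns[loc.name] = (ca, cb)
        a = gm.calls[:, l, 0]
        b = gm.calls[:, l, 1]
        data[ca] = ["" if v == MISSING else int(v) for v in a]
        data[cb] = ["" if v == MISSING else int(v) for v in b]
    layout = TableLayout(id_col="id", locus_columns=locus_columns,
                         motif_lengths={lc.name: lc.repeat_motif_length for lc in gm.loci})
    if gm.coordinates is not None:
        data["x_km"] = gm.coordinates[:, 0]
        data["y_km"] = gm.coordinates[:, 1]
        layout.x_col, layout.y_col = "x_km", "y_km"
    if gm.group_labels is not None:
        data["group"] = gm.group_labels
        layout.group_col = "group"
    if gm.sex is not None:
        data["sex"] = gm.sex
        layout.sex_col = "sex"
    if gm.age is not None:
        data["age"] = gm.age
        layout.age_col = "age"
    pd.DataFrame(data).to_csv(path, index=False)
    return layout


# ---------------------------------------------------------------------------
# Panel editing
# ---------------------------------------------------------------------------

def exclude_loci(gm: GenotypeMatrix, names: Sequence[str]) -> GenotypeMatrix:
    """Drop the named loci (e.g. a null-allele exclusion list).

    The individual set is unchanged.  Unknown names raise; removing every
    locus raises (empty panels are forbidden).
    """
    unknown = [nm for nm in names if nm not in gm.locus_names]
    if unknown:
        raise KeyError(f"unknown loci: {unknown}")
    keep = [l for l, nm in enumerate(gm.locus_names) if nm not in set(names)]
    if not keep:
        raise ValueError("cannot exclude all loci (empty panel)")
    return GenotypeMatrix(
        individual_ids=list(gm.individual_ids),
        loci=[gm.loci[l] for l in keep],
        calls=gm.calls[:, keep].copy(),
        coordinates=None if gm.coordinates is None else gm.coordinates.copy(),
        group_labels=None if gm.group_labels is None else list(gm.group_labels),
        sex=None if gm.sex is None else list(gm.sex),
        age=None if gm.age is None else list(gm.age),
    )
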