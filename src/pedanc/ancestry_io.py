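"""I/O for ancestry dosage matrices, call-quality matrices and genetic maps.

Ancestry matrices are markers x individuals TSV tables with a ``marker``
header column and integer dosages in {0,1,2} (``NA`` for missing). The
dosage counts population-A ancestry alleles (African in a two-way
African/European admixture); upstream tools with the opposite coding can be
recoded on read. Maps are 3-column TSVs (marker, chromosome, cM) or PLINK
``.bim`` files, in which case column 3 carries the cM position.

Internally all map positions stay in centiMorgans; inter-marker distances
are exposed in Morgans, the unit the transition models expect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)  # internal missing-dosage sentinel


class AncestryIOError(ValueError):
    pass


@dataclass
class GeneticMap:
    """Ordered marker positions (cM) per chromosome."""

    chroms: dict[str, tuple[list[str], np.ndarray]]  # chrom -> (ids, cM positions)

    def __post_init__(self) -> None:
        self._pos: dict[str, tuple[str, float]] = {}
        for chrom, (ids, pos) in self.chroms.items():
            pos = np.asarray(pos, dtype=float)
            if len(ids) != len(pos):
                raise AncestryIOError(f"chrom {chrom}: id/position length mismatch")
            if np.any(np.diff(pos) < 0):
                bad = int(np.flatnonzero(np.diff(pos) < 0)[0]) + 1
                raise AncestryIOError(
                    f"chrom {chrom}: positions decrease at marker {ids[bad]!r}"
                )
            if np.any(pos < 0):
                raise AncestryIOError(f"chrom {chrom}: negative cM position")
            self.chroms[chrom] = (list(ids), pos)
            for i, mid in enumerate(ids):
                if mid in self._pos:
                    raise AncestryIOError(f"duplicate marker id {mid!r} in map")
                self._pos[mid] = (chrom, float(pos[i]))

    @property
    def marker_ids(self) -> list[str]:
        return [mid for chrom in self.chroms for mid in self.chroms[chrom][0]]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._pos

    def position_cm(self, marker_id: str) -> float:
        if marker_id not in self._pos:
            raise AncestryIOError(f"unknown marker {marker_id!r}")
        return self._pos[marker_id][1]

    def chrom_of(self, marker_id: str) -> str:
        if marker_id not in self._pos:
            raise AncestryIOError(f"unknown marker {marker_id!r}")
        return self._pos[marker_id][0]

    def positions_cm(self, chrom: str) -> np.ndarray:
        return self.chroms[chrom][1]

    def distances_morgans(self, chrom: str) -> np.ndarray:
        """Adjacent inter-marker distances d_t in Morgans (length L-1)."""
        return np.diff(self.chroms[chrom][1]) / 100.0

    def subset(self, marker_ids: list[str]) -> "GeneticMap":
        """Map restricted to ``marker_ids``, preserving map order."""
        keep = set(marker_ids)
        chroms = {}
        for chrom, (ids, pos) in self.chroms.items():
            mask = [i for i, mid in enumerate(ids) if mid in keep]
            if mask:
                chroms[chrom] = ([ids[i] for i in mask], pos[mask])
        return GeneticMap(chroms=chroms)


@dataclass
class AncestryMatrix:
    """Markers x individuals diploid ancestry dosages with optional quality.

    ``dosages`` is int8 with -1 for missing; ``quality`` (if present) holds
    the upstream per-call posterior confidence in [0,1].
    """

    marker_ids: list[str]
    individual_ids: list[str]
    dosages: np.ndarray
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        L, n = self.dosages.shape
        if L != len(self.marker_ids) or n != len(self.individual_ids):
            raise AncestryIOError("dosage shape inconsistent with id lists")
        valid = np.isin(self.dosages, [-1, 0, 1, 2])
        if not valid.all():
            r, c = np.argwhere(~valid)[0]
            raise AncestryIOError(
                f"dosage out of domain at marker {self.marker_ids[r]!r}, "
                f"individual {self.individual_ids[c]!r}: {self.dosages[r, c]}"
            )
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=float)
            if self.quality.shape != self.dosages.shape:
                raise AncestryIOError("quality shape differs from dosage shape")
            finite = np.isfinite(self.quality)
            if np.any((self.quality[finite] < 0) | (self.quality[finite] > 1)):
                raise AncestryIOError("quality values must lie in [0,1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def column(self, individual_id: str) -> np.ndarray:
        return self.dosages[:, self.individual_ids.index(individual_id)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.dosages.astype(object), index=self.marker_ids, columns=self.individual_ids
        )
        df = df.mask(self.dosages == MISSING, other=pd.NA)
        df.index.name = "marker"
        return df

    def copy(self) -> "AncestryMatrix":
        return AncestryMatrix(
            marker_ids=list(self.marker_ids),
            individual_ids=list(self.individual_ids),
            dosages=self.dosages.copy(),
            quality=None if self.quality is None else self.quality.copy(),
        )


def _read_table(source) -> pd.DataFrame:
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    return pd.read_csv(source, sep="\t", dtype=str, index_col=0)


def read_ancestry_matrix(source, quality_source=None) -> AncestryMatrix:
    """Read a dosage TSV (header ``marker`` + individual ids, values in
    {0,1,2,NA}); optionally attach a same-shaped quality TSV."""
    df = _read_table(source)
    L, n = df.shape
    dosages = np.full((L, n), MISSING, dtype=np.int8)
    values = df.to_numpy()
    for r in range(L):
        for c in range(n):
            v = values[r, c]
            if pd.isna(v) or v == "NA":
                continue
            if v not in ("0", "1", "2"):
                raise AncestryIOError(
                    f"invalid dosage {v!r} at marker {df.index[r]!r}, "
                    f"individual {df.columns[c]!r}"
                )
            dosages[r, c] = int(v)
    mat = AncestryMatrix(
        marker_ids=[str(m) for m in df.index],
        individual_ids=[str(c) for c in df.columns],
        dosages=dosages,
    )
    if quality_source is not None:
        mat.quality = read_quality_matrix(quality_source, like=mat)
    return mat


def read_quality_matrix(source, like: AncestryMatrix) -> np.ndarray:
    df = _read_table(source)
    if list(df.index) != like.marker_ids or list(df.columns) != like.individual_ids:
        raise AncestryIOError("quality matrix ids do not match the dosage matrix")
    q = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return q


def write_ancestry_matrix(mat: AncestryMatrix, path_or_buffer) -> None:
    mat.to_dataframe().to_csv(path_or_buffer, sep="\t", na_rep="NA")


def write_quality_matrix(mat: AncestryMatrix, path_or_buffer) -> None:
    if mat.quality is None:
        raise AncestryIOError("matrix carries no quality values")
    df = pd.DataFrame(mat.quality, index=mat.marker_ids, columns=mat.individual_ids)
    df.index.name = "marker"
    df.to_csv(path_or_buffer, sep="\t", na_rep="NA")


def read_genetic_map(source) -> GeneticMap:
    """Read a genetic map.

    Accepts a 3-column TSV (marker, chrom, cM; optional header) or a PLINK
    ``.bim`` file (chrom, marker, cM, bp, a1, a2) detected by column count.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] >= 6:  # .bim: chrom, id, cM, bp, alleles
        df = df.iloc[:, :3]
        df.columns = ["chrom", "marker", "cM"]
    elif df.shape[1] == 3:
        df.columns = ["marker", "chrom", "cM"]
        if df.iloc[0]["marker"].lower() in ("marker", "marker_id", "id", "snp"):
            df = df.iloc[1:]
    else:
        raise AncestryIOError(f"expected 3 or >=6 map columns, got {df.shape[1]}")
    chroms: dict[str, tuple[list[str], list[float]]] = {}
    for _, row in df.iterrows():
        try:
            pos = float(row["cM"])
        except ValueError as exc:
            raise AncestryIOError(f"bad cM value {row['cM']!r} for {row['marker']!r}") from exc
        ids, positions = chroms.setdefault(str(row["chrom"]), ([], []))
        ids.append(str(row["marker"]))
        positions.append(pos)
    return GeneticMap(
        chroms={c: (ids, np.asarray(pos)) for c, (ids, pos) in chroms.items()}
    )


def write_genetic_map(gmap: GeneticMap, path_or_buffer) -> None:
    rows = []
    for chrom, (ids, pos) in gmap.chroms.items():
        for mid, p in zip(ids, pos):
            rows.append((mid, chrom, p))
    pd.DataFrame(rows, columns=["marker", "chrom", "cM"]).to_csv(
        path_or_buffer, sep="\t", index=False, header=False
    )


@dataclass
class AlignedBundle:
    """Dosage matrix, map and pedigree restricted to their common support.

    Individuals are in pedigree order; markers in map order. ``segments``
    lists per-chromosome (chrom, start, stop) row ranges so downstream
    sweeps never cross a chromosome boundary.
    """

    matrix: AncestryMatrix
    gmap: GeneticMap
    ped: "Pedigree"  # noqa: F821 - pedigree module type
    dropped_individuals: list[str] = field(default_factory=list)
    dropped_markers: list[str] = field(default_factory=list)

    @property
    def segments(self) -> list[tuple[str, int, int]]:
        out, start = [], 0
        for chrom, (ids, _) in self.gmap.chroms.items():
            out.append((chrom, start, start + len(ids)))
            start += len(ids)
        return out

    def positions_cm(self) -> np.ndarray:
        return np.concatenate(
            [self.gmap.positions_cm(chrom) for chrom in self.gmap.chroms]
        )


def align(matrix: AncestryMatrix, gmap: GeneticMap, ped) -> AlignedBundle:
    """Restrict a dosage matrix to the pedigree's individuals and the map's
    markers, reordering markers to map order. Errors if either intersection
    is empty; dropped ids/markers are reported on the bundle."""
    ped_ids = [iid for iid in ped.ids if iid in matrix.individual_ids]
    dropped_ind = [iid for iid in matrix.individual_ids if iid not in set(ped.ids)]
    dropped_ind += [iid for iid in ped.ids if iid not in set(matrix.individual_ids)]
    if not ped_ids:
        raise AncestryIOError("no individuals shared between matrix and pedigree")

    have = set(matrix.marker_ids)
    kept_markers = [mid for mid in gmap.marker_ids if mid in have]
    if not kept_markers:
        raise AncestryIOError("no markers shared between matrix and map")
    dropped_mk = [m for m in matrix.marker_ids if m not in set(kept_markers)]

    row_ix = [matrix.marker_ids.index(m) for m in kept_markers]
    col_ix = [matrix.individual_ids.index(i) for i in ped_ids]
    sub = AncestryMatrix(
        marker_ids=kept_markers,
        individual_ids=ped_ids,
        dosages=matrix.dosages[np.ix_(row_ix, col_ix)],
        quality=None
        if matrix.quality is None
        else matrix.quality[np.ix_(row_ix, col_ix)],
    )
    subped = ped.subset(ped_ids) if len(ped_ids) != ped.n else ped
    return AlignedBundle(
        matrix=sub,
        gmap=gmap.subset(kept_markers),
        ped=subped,
        dropped_individuals=dropped_ind,
        dropped_markers=dropped_mk,
    )
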