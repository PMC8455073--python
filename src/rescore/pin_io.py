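"""Reading and writing Percolator-INput (PIN) PSM tables and result files.

A PIN file is tab-delimited with the header
``SpecId  Label  ScanNr  [Rank]  <feature ...>  Peptide  Proteins``.
``Label`` is ``1`` for target PSMs and ``-1`` for decoys.  An optional second
line whose first field is ``DefaultDirection`` carries a per-feature initial
search direction instead of a PSM.  The ``Proteins`` field is the last
logical column and may itself contain tabs: every field after ``Peptide`` is
a protein identifier.  Because of that convention the file cannot be parsed
by a naive CSV reader, so the reader here splits rows explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import PinFormatError, SchemaError

__all__ = [
    "PsmTable",
    "FeatureSchema",
    "SchemaReport",
    "read_pin",
    "write_pin",
    "write_results",
    "validate_schema",
]

_RESERVED = ("SpecId", "Label", "ScanNr", "Rank", "Peptide", "Proteins")


@dataclass
class FeatureSchema:
    """An ordered list of feature names defining the model input space."""

    feature_names: list[str]

    def __post_init__(self) -> None:
        if not self.feature_names:
            raise SchemaError("a feature schema must name at least one feature")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise SchemaError("feature names must be unique")


@dataclass
class PsmTable:
    """A set of peptide-spectrum matches with target/decoy labels.

    Parameters
    ----------
    spec_id : array of str
        Unique opaque identifier per PSM.
    is_target : bool array
        True for target PSMs, False for decoys.
    scan_nr : int array
        Scan number of the spectrum each PSM was matched to. Multiple
        PSMs (candidate ranks) may share one scan.
    features : pandas.DataFrame
        Real-valued feature matrix, one row per PSM, named columns.
    peptide : array of str
        Modified peptide string, optionally with flanking residues
        (``K.PEPTIDER.S``).
    proteins : list of tuples of str
        Protein identifiers per PSM.
    rank : int array, optional
        Candidate rank within the spectrum (1 = best). Defaults to 1.
    default_direction : array, optional
        Per-feature initial search direction, as read from a PIN
        ``DefaultDirection`` row.
    """

    spec_id: np.ndarray
    is_target: np.ndarray
    scan_nr: np.ndarray
    features: pd.DataFrame
    peptide: np.ndarray
    proteins: list[tuple[str, ...]]
    rank: np.ndarray = field(default=None)  # type: ignore[assignment]
    default_direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spec_id = np.asarray(self.spec_id, dtype=object)
        self.is_target = np.asarray(self.is_target, dtype=bool)
        self.scan_nr = np.asarray(self.scan_nr, dtype=np.int64)
        self.peptide = np.asarray(self.peptide, dtype=object)
        if self.rank is None:
            self.rank = np.ones(len(self.spec_id), dtype=np.int64)
        self.rank = np.asarray(self.rank, dtype=np.int64)
        self.proteins = [tuple(p) for p in self.proteins]
        n = len(self.spec_id)
        for name, arr in [
            ("is_target", self.is_target),
            ("scan_nr", self.scan_nr),
            ("peptide", self.peptide),
            ("rank", self.rank),
        ]:
            if len(arr) != n:
                raise SchemaError(f"column {name!r} has length {len(arr)}, expected {n}")
        if len(self.proteins) != n or len(self.features) != n:
            raise SchemaError("features/proteins not aligned with spec_id")
        if n and len(set(self.spec_id)) != n:
            raise SchemaError("spec_id values must be unique")
        if (self.rank < 1).any():
            raise SchemaError("rank must be a positive integer")
        vals = self.features.to_numpy(dtype=float, copy=False)
        if vals.size and not np.isfinite(vals).all():
            raise SchemaError("feature matrix contains missing or non-finite values")
        if self.default_direction is not None:
            self.default_direction = np.asarray(self.default_direction, dtype=float)
            if len(self.default_direction) != self.features.shape[1]:
                raise SchemaError("default_direction length must match feature count")

    def __len__(self) -> int:
        return len(self.spec_id)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def feature_matrix(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def n_targets(self) -> int:
        return int(self.is_target.sum())

    @property
    def n_decoys(self) -> int:
        return int((~self.is_target).sum())

    def take(self, indices) -> "PsmTable":
        """Return a new table containing the rows at ``indices`` (in order)."""
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return PsmTable(
            spec_id=self.spec_id[idx],
            is_target=self.is_target[idx],
            scan_nr=self.scan_nr[idx],
            features=self.features.iloc[idx].reset_index(drop=True),
            peptide=self.peptide[idx],
            proteins=[self.proteins[i] for i in idx],
            rank=self.rank[idx],
            default_direction=self.default_direction,
        )

    def equals(self, other: "PsmTable") -> bool:
        """Exact equality of all fields, including full-precision features."""
        if len(self) != len(other) or self.feature_names != other.feature_names:
            return False
        same_dd = (
            (self.default_direction is None and other.default_direction is None)
            or (
                self.default_direction is not None
                and other.default_direction is not None
                and np.array_equal(self.default_direction, other.default_direction)
            )
        )
        return bool(
            same_dd
            and np.array_equal(self.spec_id, other.spec_id)
            and np.array_equal(self.is_target, other.is_target)
            and np.array_equal(self.scan_nr, other.scan_nr)
            and np.array_equal(self.rank, other.rank)
            and np.array_equal(self.peptide, other.peptide)
            and self.proteins == other.proteins
            and np.array_equal(self.feature_matrix, other.feature_matrix)
        )


@dataclass
class SchemaReport:
    """Result of checking a table against a model's feature schema."""

    compatible: bool
    missing: list[str]
    extra: list[str]


def _parse_label(token: str, line_no: int) -> bool:
    if token == "1":
        return True
    if token == "-1":
        return False
    raise PinFormatError(f"line {line_no}: unknown Label value {token!r} (expected 1 or -1)")


def read_pin(path) -> PsmTable:
    """Read a PIN-format file into a :class:`PsmTable`.

    Raises :class:`PinFormatError` on a malformed header, an unknown label,
    or a non-numeric feature cell (missing values are not imputed).
    """
    with open(path, "r", encoding="utf-8") as handle:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in handle]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise PinFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    for required in ("SpecId", "Label", "ScanNr", "Peptide", "Proteins"):
        if required not in header:
            raise PinFormatError(f"{path}: header is missing required column {required!r}")
    if header[:3] != ["SpecId", "Label", "ScanNr"]:
        raise PinFormatError(f"{path}: header must start with SpecId, Label, ScanNr")
    has_rank = len(header) > 3 and header[3] == "Rank"
    pep_idx = header.index("Peptide")
    if header.index("Proteins") != pep_idx + 1 or pep_idx != len(header) - 2:
        raise PinFormatError(f"{path}: Peptide and Proteins must be the last two header columns")
    feat_start = 4 if has_rank else 3
    feature_names = header[feat_start:pep_idx]
    if not feature_names:
        raise PinFormatError(f"{path}: header declares no feature columns")
    if len(set(feature_names)) != len(feature_names):
        raise PinFormatError(f"{path}: duplicate feature names in header")

    body = lines[1:]
    default_direction = None
    if body and body[0].split("\t")[0] == "DefaultDirection":
        fields = body[0].split("\t")
        try:
            default_direction = np.array(
                [float(fields[i]) for i in range(feat_start, pep_idx)], dtype=float
            )
        except (ValueError, IndexError) as exc:
            raise PinFormatError(f"{path}: malformed DefaultDirection row") from exc
        body = body[1:]

    spec_id, is_target, scan_nr, rank, peptide, proteins = [], [], [], [], [], []
    feat_rows = []
    for offset, line in enumerate(body):
        line_no = offset + 2 + (default_direction is not None)
        fields = line.split("\t")
        if len(fields) < pep_idx + 2:
            raise PinFormatError(
                f"{path}: line {line_no} has {len(fields)} fields, expected >= {pep_idx + 2}"
            )
        spec_id.append(fields[0])
        is_target.append(_parse_label(fields[1], line_no))
        try:
            scan_nr.append(int(fields[2]))
        except ValueError as exc:
            raise PinFormatError(f"{path}: line {line_no}: non-integer ScanNr {fields[2]!r}") from exc
        if has_rank:
            try:
                rank.append(int(fields[3]))
            except ValueError as exc:
                raise PinFormatError(f"{path}: line {line_no}: non-integer Rank {fields[3]!r}") from exc
        row = []
        for j, name in enumerate(feature_names):
            cell = fields[feat_start + j]
            try:
                row.append(float(cell))
            except ValueError as exc:
                raise PinFormatError(
                    f"{path}: line {line_no}, column {name!r}: non-numeric value {cell!r}"
                ) from exc
        feat_rows.append(row)
        peptide.append(fields[pep_idx])
        proteins.append(tuple(fields[pep_idx + 1 :]))

    features = pd.DataFrame(
        np.array(feat_rows, dtype=float).reshape(len(spec_id), len(feature_names)),
        columns=feature_names,
    )
    return PsmTable(
        spec_id=np.array(spec_id, dtype=object),
        is_target=np.array(is_target, dtype=bool),
        scan_nr=np.array(scan_nr, dtype=np.int64),
        features=features,
        peptide=np.array(peptide, dtype=object),
        proteins=proteins,
        rank=np.array(rank, dtype=np.int64) if has_rank else None,
        default_direction=default_direction,
    )


def _fmt(x: float) -> str:
    # repr() gives the shortest string that round-trips the float exactly
    return repr(float(x))


def write_pin(table: PsmTable, path) -> None:
    """Write a :class:`PsmTable` as a PIN file; lossless round-trip with
    :func:`read_pin` (features at full decimal precision)."""
    has_rank = bool((table.rank != 1).any())
    header = ["SpecId", "Label", "ScanNr"]
    if has_rank:
        header.append("Rank")
    header += table.feature_names + ["Peptide", "Proteins"]
    mat = table.feature_matrix
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(header) + "\n")
        if table.default_direction is not None:
            dd = ["DefaultDirection", "-", "-"] + (["-"] if has_rank else [])
            dd += [_fmt(v) for v in table.default_direction] + ["-", "-"]
            out.write("\t".join(dd) + "\n")
        for i in range(len(table)):
            fields = [
                str(table.spec_id[i]),
                "1" if table.is_target[i] else "-1",
                str(int(table.scan_nr[i])),
            ]
            if has_rank:
                fields.append(str(int(table.rank[i])))
            fields += [_fmt(v) for v in mat[i]]
            fields.append(str(table.peptide[i]))
            fields.extend(table.proteins[i])
            out.write("\t".join(fields) + "\n")


def _write_level(frame: pd.DataFrame, id_header: str, path) -> None:
    frame = frame.sort_values(
        ["score", "spec_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join([id_header, "score", "q-value", "peptide", "proteins"]) + "\n")
        for row in frame.itertuples(index=False):
            out.write(
                "\t".join(
                    [
                        str(row.spec_id),
                        _fmt(row.score),
                        format(row.qvalue, ".6g"),
                        str(row.peptide),
                        "\t".join(row.proteins),
                    ]
                )
                + "\n"
            )


def write_results(result, prefix) -> None:
    """Write PSM- and peptide-level result tables as ``<prefix>.psms.txt``
    and ``<prefix>.peptides.txt``.

    Rows are sorted by decreasing score (ties broken by identifier) and
    q-values are printed with six significant digits. The peptide file has
    one row per distinct peptide, identified by its best-scoring PSM.
    """
    cols = ["spec_id", "score", "qvalue", "peptide", "proteins"]
    _write_level(result.psm_table[cols], "PSMId", f"{prefix}.psms.txt")
    _write_level(result.peptide_table[cols], "PSMId", f"{prefix}.peptides.txt")


def validate_schema(table: PsmTable, schema: FeatureSchema | list[str]) -> SchemaReport:
    """Check whether ``table`` provides every feature a model expects.

    The table is compatible iff the schema's features are a subset of the
    table's; extra table features are reported but harmless.
    """
    names = schema.feature_names if isinstance(schema, FeatureSchema) else list(schema)
    have = set(table.feature_names)
    want = set(names)
    missing = sorted(want - have)
    extra = sorted(have - want)
    return SchemaReport(compatible=not missing, missing=missing, extra=extra)
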