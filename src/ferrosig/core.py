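"""Domain types and file I/O.

Containers for the objects every stage of the pipeline passes around:
expression matrices (genes x observations), ferroptosis-regulator
catalogs, gene sets, perturbation-profile libraries, and drug-response
tables.  Readers and writers cover the plain-text formats the tool
exchanges with the outside world: Matrix Market triplet directories,
dense TSV/CSV, GMT gene sets, and TSV/parquet perturbation matrices.

Gene identifiers are plain HGNC-style symbols, upper-cased at load time
so matching is case-insensitive everywhere; no alias resolution is
attempted.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: Significant digits used when serialising floats to TSV; enough for a
#: bit-exact float64 round trip.
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class Layer(str, enum.Enum):
    """What the values of an expression matrix represent."""

    RAW_COUNTS = "raw_counts"
    LOG_NORMALIZED = "log_normalized"
    ZSCORE = "zscore"


class Role(str, enum.Enum):
    """Direction in which a gene acts on ferroptosis."""

    DRIVER = "driver"
    SUPPRESSOR = "suppressor"


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({x for x in ids if x in seen or seen.add(x)})
        raise FormatError(f"duplicate {what}: {', '.join(dups[:10])}")


@dataclass
class ExpressionMatrix:
    """A genes x observations expression matrix.

    Parameters
    ----------
    values
        2-D array, rows are genes and columns are observations (cells or
        samples).
    gene_ids, obs_ids
        Unique row / column identifiers.
    condition
        Optional per-observation group label (e.g. ``"sensitive"`` /
        ``"resistant"``); defaults to a single group.
    layer
        Semantics of ``values``: raw UMI counts, log-normalized
        expression, or per-gene z-scores.
    """

    values: np.ndarray
    gene_ids: list[str]
    obs_ids: list[str]
    condition: np.ndarray | None = None
    layer: Layer = Layer.RAW_COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.gene_ids = [str(g).upper() for g in self.gene_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        self.layer = Layer(self.layer)
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        _check_unique(self.gene_ids, "gene symbols")
        _check_unique(self.obs_ids, "observation ids")
        if self.condition is not None:
            self.condition = np.asarray(self.condition, dtype=object)
            if self.condition.shape != (len(self.obs_ids),):
                raise ValueError("condition must have one label per observation")
        if self.layer is Layer.RAW_COUNTS:
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise ValueError("raw_counts layer requires non-negative integers")
        if self.layer is Layer.ZSCORE:
            sd = self.values.std(axis=1, ddof=1) if self.n_obs > 1 else None
            if sd is not None:
                nz = sd > 0
                mu = self.values[nz].mean(axis=1)
                if nz.any() and (
                    np.max(np.abs(mu), initial=0.0) > 1e-8
                    or np.max(np.abs(sd[nz] - 1.0), initial=0.0) > 1e-8
                ):
                    raise ValueError("zscore layer rows must have mean 0 and sd 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset(
        self,
        genes: Sequence[str] | None = None,
        obs: Sequence[str] | np.ndarray | None = None,
    ) -> "ExpressionMatrix":
        """Return a copy restricted to the given genes and/or observations.

        ``obs`` may be a boolean mask over columns or a list of ids.
        """
        gi = np.arange(self.n_genes)
        oi = np.arange(self.n_obs)
        if genes is not None:
            idx = self.gene_index()
            gi = np.array([idx[g.upper()] for g in genes])
        if obs is not None:
            obs_arr = np.asarray(obs)
            if obs_arr.dtype == bool:
                oi = np.flatnonzero(obs_arr)
            else:
                idx_o = {o: i for i, o in enumerate(self.obs_ids)}
                oi = np.array([idx_o[o] for o in obs_arr])
        return ExpressionMatrix(
            values=self.values[np.ix_(gi, oi)].copy(),
            gene_ids=[self.gene_ids[i] for i in gi],
            obs_ids=[self.obs_ids[i] for i in oi],
            condition=None if self.condition is None else self.condition[oi].copy(),
            layer=self.layer,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.obs_ids)


@dataclass
class RegulatorCatalog:
    """Mapping gene symbol -> ferroptosis role (driver or suppressor)."""

    entries: dict[str, Role]
    source_label: str = ""

    def __post_init__(self) -> None:
        self.entries = {str(g).upper(): Role(r) for g, r in self.entries.items()}
        if not self.entries:
            raise ValueError("catalog is empty")

    def genes_with_role(self, role: Role | str) -> list[str]:
        role = Role(role)
        return [g for g, r in self.entries.items() if r is role]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.entries


@dataclass
class GeneSet:
    """A named, non-empty collection of unique gene symbols."""

    name: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        self.members = [str(g).upper() for g in self.members]
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        _check_unique(self.members, f"members of gene set {self.name!r}")


@dataclass
class PerturbationLibrary:
    """Genes x instances matrix of perturbation ranking statistics.

    Each column ("instance") holds differential-expression statistics --
    LINCS-style moderated z-scores -- for one compound treatment, and
    ``metadata`` carries at least the instance id and compound name.
    """

    stat_matrix: np.ndarray
    gene_ids: list[str]
    instance_ids: list[str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.stat_matrix = np.asarray(self.stat_matrix, dtype=float)
        self.gene_ids = [str(g).upper() for g in self.gene_ids]
        self.instance_ids = [str(i) for i in self.instance_ids]
        if self.stat_matrix.shape != (len(self.gene_ids), len(self.instance_ids)):
            raise ValueError("stat_matrix shape inconsistent with id lists")
        _check_unique(self.gene_ids, "gene symbols")
        _check_unique(self.instance_ids, "instance ids")
        bad = np.argwhere(~np.isfinite(self.stat_matrix))
        if bad.size:
            g, i = bad[0]
            raise ValueError(
                f"non-finite statistic at gene {self.gene_ids[g]!r}, "
                f"instance {self.instance_ids[i]!r}"
            )
        if "instance_id" not in self.metadata.columns:
            raise ValueError("metadata must contain an instance_id column")
        meta_ids = [str(i) for i in self.metadata["instance_id"]]
        if sorted(meta_ids) != sorted(self.instance_ids):
            raise ValueError("metadata rows do not match matrix instance columns")
        # align metadata to column order
        self.metadata = (
            self.metadata.assign(instance_id=meta_ids)
            .set_index("instance_id")
            .loc[self.instance_ids]
            .reset_index()
        )

    @property
    def n_instances(self) -> int:
        return len(self.instance_ids)

    def profile(self, instance_id: str) -> pd.Series:
        """Ranking statistics of one instance, indexed by gene symbol."""
        j = self.instance_ids.index(instance_id)
        return pd.Series(self.stat_matrix[:, j], index=self.gene_ids, name=instance_id)


@dataclass
class ResponseTable:
    """Per-sample drug-response scalars (AUC or IC50-like)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "response_value"}
        if not required.issubset(self.table.columns):
            raise ValueError("response table needs sample_id and response_value columns")
        self.table = self.table.copy()
        self.table["sample_id"] = self.table["sample_id"].astype(str)
        _check_unique(list(self.table["sample_id"]), "sample ids")
        if not np.all(np.isfinite(self.table["response_value"].to_numpy(float))):
            raise ValueError("response values must be finite")


# ---------------------------------------------------------------------------
# expression I/O


def _read_labels(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"label file {path} needs two columns (obs_id, condition)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_expression(
    path: str | Path,
    format: str = "dense_tsv",
    layer: Layer | str = Layer.RAW_COUNTS,
    labels_path: str | Path | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``format="mtx_dir"`` expects a directory with ``matrix.mtx``,
    ``genes.tsv`` and ``barcodes.tsv`` (10x-style triplet, 1-based
    coordinates); an optional ``conditions.tsv`` sidecar maps barcodes to
    group labels.  ``format="dense_tsv"`` expects genes as rows with a
    header of observation ids (pass ``transpose=True`` for the other
    orientation); group labels come from ``labels_path``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx_dir":
        for name in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
            if not (path / name).exists():
                raise FormatError(f"missing companion file {name} in {path}")
        mat = scipy.io.mmread(path / "matrix.mtx")
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None).iloc[:, 0]
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None).iloc[:, 0]
        gene_ids = [str(g) for g in genes]
        obs_ids = [str(b) for b in barcodes]
        label_file = path / "conditions.tsv"
        labels = _read_labels(label_file) if label_file.exists() else None
        if labels_path is not None:
            labels = _read_labels(Path(labels_path))
    elif format == "dense_tsv":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        if transpose:
            df = df.T
        values = df.to_numpy()
        gene_ids = [str(g) for g in df.index]
        obs_ids = [str(o) for o in df.columns]
        labels = _read_labels(Path(labels_path)) if labels_path is not None else None
    else:
        raise ValueError(f"unknown expression format {format!r}")
    condition = None
    if labels is not None:
        try:
            condition = np.array([labels[o] for o in obs_ids], dtype=object)
        except KeyError as exc:
            raise FormatError(f"observation {exc.args[0]!r} missing from labels") from None
    return ExpressionMatrix(values, gene_ids, obs_ids, condition=condition, layer=layer)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, format: str = "dense_tsv"
) -> None:
    """Write an expression matrix as a dense TSV or an MTX triplet directory."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", scipy.sparse.coo_matrix(matrix.values))
        (path / "genes.tsv").write_text("".join(f"{g}\n" for g in matrix.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in matrix.obs_ids))
        if matrix.condition is not None:
            lines = ["obs_id\tcondition\n"] + [
                f"{o}\t{c}\n" for o, c in zip(matrix.obs_ids, matrix.condition)
            ]
            (path / "conditions.tsv").write_text("".join(lines))
    elif format == "dense_tsv":
        path.parent.mkdir(parents=True, exist_ok=True)
        matrix.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# catalog I/O


def read_catalog(path: str | Path) -> RegulatorCatalog:
    """Read a two-column (gene, role) regulator catalog TSV.

    Genes annotated with both roles are excluded (the signed FR20 weight
    is undefined for them) and the exclusion is logged; rows whose role
    is neither ``driver`` nor ``suppressor`` raise an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise FormatError(f"catalog {path} has no entries")
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "role" not in cols:
        raise FormatError(f"catalog {path} needs 'gene' and 'role' columns")
    roles: dict[str, set[str]] = {}
    for gene, role in zip(df[cols["gene"]], df[cols["role"]]):
        role = str(role).strip().lower()
        if role not in (Role.DRIVER.value, Role.SUPPRESSOR.value):
            raise FormatError(f"unknown role {role!r} for gene {gene!r}")
        roles.setdefault(str(gene).upper(), set()).add(role)
    dual = sorted(g for g, rs in roles.items() if len(rs) > 1)
    if dual:
        logger.warning(
            "excluding %d dual-annotated gene(s) (driver and suppressor): %s",
            len(dual),
            ", ".join(dual),
        )
    entries = {g: Role(next(iter(rs))) for g, rs in roles.items() if len(rs) == 1}
    if not entries:
        raise FormatError(f"catalog {path} is empty after dual-annotation filtering")
    return RegulatorCatalog(entries=entries, source_label=str(path))


def write_catalog(catalog: RegulatorCatalog, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [f"{g}\t{r.value}\n" for g, r in sorted(catalog.entries.items())]
    path.write_text("gene\trole\n" + "".join(rows))


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{ln}: GMT line needs name, description, members")
        sets.append(GeneSet(name=fields[0], members=fields[2:]))
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path, description: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "\t".join([s.name, description] + list(s.members)) + "\n" for s in sets
    ]
    path.write_text("".join(lines))


# ---------------------------------------------------------------------------
# perturbation library I/O


def read_perturbations(
    matrix_path: str | Path, metadata_path: str | Path
) -> PerturbationLibrary:
    """Read a perturbation-statistic matrix (TSV or parquet) and its metadata.

    The matrix has genes as rows and instance ids as column header; the
    metadata TSV needs ``instance_id`` and ``compound_name`` columns with
    exactly one row per matrix column.
    """
    matrix_path = Path(matrix_path)
    metadata_path = Path(metadata_path)
    for p in (matrix_path, metadata_path):
        if not p.exists():
            raise FileNotFoundError(p)
    if matrix_path.suffix == ".parquet":
        df = pd.read_parquet(matrix_path)
        df = df.set_index(df.columns[0])
    else:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "compound_name" not in meta.columns:
        raise FormatError(f"{metadata_path}: metadata needs a compound_name column")
    return PerturbationLibrary(
        stat_matrix=df.to_numpy(float),
        gene_ids=[str(g) for g in df.index],
        instance_ids=[str(c) for c in df.columns],
        metadata=meta,
    )


def write_perturbations(
    library: PerturbationLibrary,
    matrix_path: str | Path,
    metadata_path: str | Path,
) -> None:
    matrix_path = Path(matrix_path)
    matrix_path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        library.stat_matrix, index=library.gene_ids, columns=library.instance_ids
    )
    if matrix_path.suffix == ".parquet":
        df.reset_index(names="gene").to_parquet(matrix_path, index=False)
    else:
        df.to_csv(matrix_path, sep="\t", float_format=_FLOAT_FMT, index_label="gene")
    library.metadata.to_csv(metadata_path, sep="\t", index=False)


def read_response(path: str | Path) -> ResponseTable:
    """Read a per-sample response TSV with sample_id and response_value."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    return ResponseTable(table=df)
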