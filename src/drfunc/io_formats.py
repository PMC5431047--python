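"""Readers, writers and background derivation for the tool's text formats.

Expression matrices are tab-separated, genes in rows and samples in columns,
with a header row of sample identifiers and gene identifiers in the first
column.  Phenotype files are two-column TSV mapping sample id to ``case`` or
``control``.  Gene sets use the standard GMT dialect (set name, description,
then member genes, all tab-separated).  All identifier matching is exact,
case-sensitive string equality.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("drfunc")

CASE = "case"
CONTROL = "control"
VALID_LABELS = frozenset({CASE, CONTROL})


class FormatError(ValueError):
    """A malformed input file (bad header, non-numeric cell, bad GMT line)."""


@dataclass
class ExpressionDataset:
    """A gene-by-sample numeric matrix with a case/control sample partition.

    Only within-sample relative orderings of the values are ever used
    downstream, so the values may be on any scale (raw intensity, log,
    counts, TPM ...) and the two phenotype groups may originate from
    different experiments or platforms.
    """

    gene_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float64
    sample_ids: list[str]
    phenotype: dict[str, str]  # sample_id -> "case" | "control"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample identifiers must be unique")
        for sid in self.sample_ids:
            label = self.phenotype.get(sid)
            if label not in VALID_LABELS:
                raise ValueError(
                    f"sample {sid!r} has phenotype {label!r}; expected one of "
                    f"{sorted(VALID_LABELS)}"
                )

    @property
    def case_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.phenotype[s] == CASE]

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.phenotype[s] == CONTROL]

    def sample_indices(self, label: str) -> np.ndarray:
        """Column indices of samples with the given phenotype label."""
        return np.array(
            [k for k, s in enumerate(self.sample_ids) if self.phenotype[s] == label],
            dtype=np.intp,
        )

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def require_min_group_sizes(self, minimum: int = 2) -> None:
        n_case, n_control = len(self.case_ids), len(self.control_ids)
        if n_case < minimum or n_control < minimum:
            raise ValueError(
                f"need at least {minimum} samples per phenotype for pair "
                f"detection; got {n_case} case and {n_control} control"
            )


@dataclass
class GeneSetCollection:
    """Named pathways (flat gene sets) plus, once derived, the background.

    ``background_genes`` is the set of genes both measured in the expression
    matrix and annotated in at least one pathway; it defines the universe N
    from which the N(N-1)/2 background gene pairs are formed.
    """

    sets: dict[str, set[str]]
    background_genes: set[str] | None = None
    source_label: str = ""

    def background_pair_count(self) -> int:
        if self.background_genes is None:
            raise ValueError("background not derived; call define_background first")
        n = len(self.background_genes)
        return n * (n - 1) // 2


def sha256_of_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_phenotype(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of (sample_id, case|control)."""
    phenotype: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got "
                    f"{len(fields)}"
                )
            sid, label = fields
            if lineno == 1 and (sid, label) == ("sample_id", "label"):
                continue  # optional canonical header
            if label not in VALID_LABELS:
                raise FormatError(
                    f"{path}:{lineno}: phenotype label {label!r} is not one of "
                    f"{sorted(VALID_LABELS)}"
                )
            if sid in phenotype:
                raise FormatError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            phenotype[sid] = label
    if not phenotype:
        raise FormatError(f"{path}: no phenotype assignments found")
    return phenotype


def read_expression(path: str | Path, phenotype_path: str | Path) -> ExpressionDataset:
    """Load an expression TSV plus its phenotype file into a dataset.

    Row order from the file is preserved.  Duplicate gene ids are collapsed
    to the row with the largest mean expression (the usual probe-collapse
    convention).  Rows containing missing values are dropped with a warning.
    Samples present in the matrix but absent from the phenotype file are
    dropped with a warning; a phenotype sample missing from the matrix is a
    hard error.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: could not parse expression matrix: {exc}") from exc
    if frame.columns.size == 0:
        raise FormatError(f"{path}: header row contains no sample columns")
    if frame.columns.duplicated().any():
        dups = frame.columns[frame.columns.duplicated()].tolist()
        raise FormatError(f"{path}: duplicated sample ids in header: {dups}")

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {frame.iat[r, c]!r} at gene "
            f"{frame.index[r]!r}, sample {frame.columns[c]!r}"
        )

    missing_rows = numeric.isna().any(axis=1)
    if missing_rows.any():
        dropped = numeric.index[missing_rows].tolist()
        logger.warning(
            "%s: dropping %d gene row(s) with missing values: %s%s",
            path, len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
        numeric = numeric.loc[~missing_rows]

    if numeric.index.duplicated().any():
        dup_ids = sorted(set(numeric.index[numeric.index.duplicated()]))
        logger.warning(
            "%s: %d duplicated gene id(s) collapsed to the row with largest "
            "mean expression: %s%s",
            path, len(dup_ids), dup_ids[:5], "..." if len(dup_ids) > 5 else "",
        )
        means = numeric.mean(axis=1).to_numpy()
        keep = np.zeros(len(numeric), dtype=bool)
        best: dict[str, int] = {}
        for pos, gid in enumerate(numeric.index):
            prev = best.get(gid)
            if prev is None or means[pos] > means[prev]:
                best[gid] = pos
        keep[list(best.values())] = True
        numeric = numeric.iloc[keep]

    phenotype = read_phenotype(phenotype_path)
    matrix_samples = set(numeric.columns)
    absent = sorted(set(phenotype) - matrix_samples)
    if absent:
        raise FormatError(
            f"{phenotype_path}: sample(s) {absent} not present in the "
            f"expression matrix {path}"
        )
    unassigned = [s for s in numeric.columns if s not in phenotype]
    if unassigned:
        logger.warning(
            "%s: dropping %d sample(s) absent from the phenotype file: %s%s",
            path, len(unassigned), unassigned[:5],
            "..." if len(unassigned) > 5 else "",
        )
        numeric = numeric.drop(columns=unassigned)

    dataset = ExpressionDataset(
        gene_ids=[str(g) for g in numeric.index],
        values=numeric.to_numpy(dtype=np.float64),
        sample_ids=[str(s) for s in numeric.columns],
        phenotype={s: phenotype[s] for s in numeric.columns},
    )
    dataset.require_min_group_sizes(2)
    return dataset


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the matrix as TSV with full float precision (round-trip safe)."""
    frame = pd.DataFrame(
        dataset.values, index=dataset.gene_ids, columns=dataset.sample_ids
    )
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def write_phenotype(dataset: ExpressionDataset, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in dataset.sample_ids:
            fh.write(f"{sid}\t{dataset.phenotype[sid]}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file; the background is not yet derived."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} has no genes")
            sets[name] = genes
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, source_label=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.sets:
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def define_background(
    dataset: ExpressionDataset, collection: GeneSetCollection
) -> GeneSetCollection:
    """Derive the analysis background: measured genes annotated in >=1 set.

    Returns a new collection whose pathways are intersected with the
    background, so each pathway's effective gene count g directly yields its
    g(g-1)/2 background gene pairs.  Idempotent and independent of pathway
    order.  An empty background (disjoint identifier spaces) is a hard error.
    """
    measured = set(dataset.gene_ids)
    annotated: set[str] = set().union(*collection.sets.values())
    background = measured & annotated
    if not background:
        raise ValueError(
            "no overlap between expression matrix gene ids and pathway gene "
            "ids; the two inputs appear to use different identifier spaces"
        )
    effective = {name: genes & background for name, genes in collection.sets.items()}
    return replace(collection, sets=effective, background_genes=background)


def provenance_lines(tool_version: str, params: dict, input_hashes: dict) -> list[str]:
    """Commented provenance header for result TSVs."""
    parts = [f"{k}={v}" for k, v in params.items()]
    hashes = [f"{k}:sha256:{v}" for k, v in input_hashes.items()]
    return [
        f"# drfunc {tool_version} | " + " ".join(parts),
        "# inputs " + " ".join(hashes) if hashes else "# inputs none",
    ]


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    tool_version: str,
    params: dict,
    input_hashes: dict,
) -> None:
    """Write a result table as TSV with a commented provenance header."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in provenance_lines(tool_version, params, input_hashes):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a result TSV written by :func:`write_table` (skips # comments)."""
    return pd.read_csv(path, sep="\t", comment="#")
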