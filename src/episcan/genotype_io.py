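"""Case/control genotype tables in additive coding.

A dataset couples a binary disease phenotype (1 = case, 0 = control) with an
individuals x SNPs matrix of additive genotype scores: 0, 1 or 2 copies of the
minor allele, or a missing value. Two plain-text layouts are supported:

* canonical: tab-delimited, header ``PHENO<TAB>snp1<TAB>snp2...``, one row per
  individual holding the phenotype followed by genotype scores; missing
  genotypes are written as ``NA``.
* transposed: one row per SNP (SNP id first, then one genotype per
  individual), with phenotypes in a separate single-column file.

An optional side-car annotation file (tab-delimited ``SNP_ID<TAB>GENE``) maps
SNPs to gene labels. All readers tolerate LF and CRLF line endings.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

#: Internal sentinel for a missing genotype; distinct from the valid scores 0/1/2.
MISSING: int = -1

#: On-disk token for a missing genotype.
MISSING_TOKEN: str = "NA"

_VALID_TOKENS = {"0": 0, "1": 1, "2": 2, MISSING_TOKEN: MISSING}

DIALECTS = ("canonical", "transposed")


class DatasetFormatError(ValueError):
    """Raised when a file cannot be parsed or violates dataset invariants."""


class UndefinedMAFError(ValueError):
    """Raised when a minor-allele frequency is requested for an all-missing column."""


@dataclasses.dataclass
class GenotypeDataset:
    """Phenotypes, additive genotypes and SNP metadata for one study.

    Parameters
    ----------
    phenotype : ndarray of shape (n_individuals,)
        Binary disease status, 1 = case and 0 = control.
    genotypes : ndarray of shape (n_individuals, n_snps)
        Additive genotype scores in {0, 1, 2, MISSING}.
    snp_ids : list of str
        Unique identifier per SNP, in column order.
    gene_names : list of str
        Optional gene label per SNP; empty list when no annotation is attached.
    """

    phenotype: np.ndarray
    genotypes: np.ndarray
    snp_ids: list[str]
    gene_names: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise DatasetFormatError("genotypes must be a 2-D individuals x SNPs matrix")
        self.snp_ids = list(self.snp_ids)
        self.gene_names = list(self.gene_names)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        n, m = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise DatasetFormatError(
                f"phenotype length {self.phenotype.shape[0]} does not match "
                f"{n} genotype rows"
            )
        bad = ~np.isin(self.phenotype, (0, 1))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise DatasetFormatError(
                f"phenotype value {self.phenotype[i]} for individual {i} is not 0 or 1"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = (int(k[0]) for k in np.nonzero(bad))
            raise DatasetFormatError(
                f"genotype value {self.genotypes[i, j]} at individual {i}, "
                f"SNP {self.snp_ids[j] if j < len(self.snp_ids) else j} is not 0/1/2/NA"
            )
        if len(self.snp_ids) != m:
            raise DatasetFormatError(
                f"{len(self.snp_ids)} SNP ids for {m} genotype columns"
            )
        if len(set(self.snp_ids)) != m:
            seen: set[str] = set()
            dup = next(s for s in self.snp_ids if s in seen or seen.add(s))  # type: ignore[func-returns-value]
            raise DatasetFormatError(f"duplicate SNP id {dup!r}")
        if self.gene_names and len(self.gene_names) != m:
            raise DatasetFormatError(
                f"{len(self.gene_names)} gene names for {m} SNPs"
            )

    # -- derived counts -----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return int(self.phenotype.shape[0])

    @property
    def n_snps(self) -> int:
        return int(self.genotypes.shape[1])

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.phenotype == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.phenotype == 0))

    def gene_of(self, j: int) -> str:
        """Gene label of SNP column *j*, or '' when unannotated."""
        return self.gene_names[j] if self.gene_names else ""

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            np.array_equal(self.phenotype, other.phenotype)
            and np.array_equal(self.genotypes, other.genotypes)
            and self.snp_ids == other.snp_ids
            and self.gene_names == other.gene_names
        )


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------


def _read_lines(path: str | Path) -> list[list[str]]:
    """Split a text file into tab-separated token rows (LF/CRLF tolerant)."""
    rows: list[list[str]] = []
    with open(path, "r", newline=None) as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if line == "":
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise DatasetFormatError(f"{path}: file is empty")
    return rows


def _parse_genotype(token: str, line_no: int, snp_id: str) -> int:
    try:
        return _VALID_TOKENS[token]
    except KeyError:
        raise DatasetFormatError(
            f"line {line_no}: genotype value {token!r} at SNP {snp_id!r} "
            f"is not one of 0/1/2/{MISSING_TOKEN}"
        ) from None


def _parse_phenotype(token: str, line_no: int, recode_12: bool = False) -> int:
    mapping = {"1": 0, "2": 1} if recode_12 else {"0": 0, "1": 1}
    try:
        return mapping[token]
    except KeyError:
        expected = "1/2 (1=control, 2=case)" if recode_12 else "0/1"
        raise DatasetFormatError(
            f"line {line_no}: phenotype value {token!r} is not {expected}"
        ) from None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_dataset(
    path: str | Path,
    dialect: str = "canonical",
    *,
    phenotype_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
    recode_pheno_12: bool = False,
) -> GenotypeDataset:
    """Read a genotype dataset from disk.

    Parameters
    ----------
    path : path
        The genotype file.
    dialect : {"canonical", "transposed"}
        File layout; the transposed layout requires ``phenotype_path``.
    phenotype_path : path, optional
        Single-column phenotype file accompanying the transposed layout.
    annotation_path : path, optional
        Side-car ``SNP_ID<TAB>GENE`` annotation file.
    recode_pheno_12 : bool
        Interpret phenotypes coded 1 = control / 2 = case and remap to 0/1.

    Returns
    -------
    GenotypeDataset
        Validated dataset preserving the file's individual and SNP order.
    """
    if dialect == "canonical":
        data = _read_canonical(path, recode_pheno_12)
    elif dialect == "transposed":
        if phenotype_path is None:
            raise DatasetFormatError(
                "the transposed dialect requires a separate phenotype file"
            )
        data = _read_transposed(path, phenotype_path, recode_pheno_12)
    else:
        raise DatasetFormatError(
            f"unknown dialect {dialect!r}; expected one of {DIALECTS}"
        )
    if annotation_path is not None:
        annot = read_annotations(annotation_path)
        data.gene_names = [annot.get(s, "") for s in data.snp_ids]
    return data


def _read_canonical(path: str | Path, recode_12: bool) -> GenotypeDataset:
    rows = _read_lines(path)
    header = rows[0]
    if header[0] != "PHENO":
        raise DatasetFormatError(
            f"{path}: header must start with 'PHENO', found {header[0]!r}"
        )
    snp_ids = header[1:]
    width = len(header)
    phen: list[int] = []
    geno: list[list[int]] = []
    for line_no, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise DatasetFormatError(
                f"{path}: line {line_no}: expected {width} fields, found {len(row)}"
            )
        phen.append(_parse_phenotype(row[0], line_no, recode_12))
        geno.append(
            [_parse_genotype(t, line_no, snp_ids[j]) for j, t in enumerate(row[1:])]
        )
    genotypes = np.array(geno, dtype=np.int8).reshape(len(geno), len(snp_ids))
    return GenotypeDataset(np.array(phen, dtype=np.int8), genotypes, snp_ids)


def _read_transposed(
    path: str | Path, phenotype_path: str | Path, recode_12: bool
) -> GenotypeDataset:
    rows = _read_lines(path)
    n_ind = len(rows[0]) - 1
    snp_ids: list[str] = []
    columns: list[list[int]] = []
    for line_no, row in enumerate(rows, start=1):
        if len(row) != n_ind + 1:
            raise DatasetFormatError(
                f"{path}: line {line_no}: expected {n_ind + 1} fields, found {len(row)}"
            )
        snp_ids.append(row[0])
        columns.append(
            [_parse_genotype(t, line_no, row[0]) for t in row[1:]]
        )
    phen_rows = _read_lines(phenotype_path)
    phen = [
        _parse_phenotype(r[0], i, recode_12) for i, r in enumerate(phen_rows, start=1)
    ]
    if len(phen) != n_ind:
        raise DatasetFormatError(
            f"{phenotype_path}: {len(phen)} phenotypes for {n_ind} individuals"
        )
    genotypes = np.array(columns, dtype=np.int8).T
    if genotypes.size == 0:
        genotypes = genotypes.reshape(n_ind, len(snp_ids))
    return GenotypeDataset(np.array(phen, dtype=np.int8), genotypes, snp_ids)


def convert_dataset(
    path: str | Path,
    source_dialect: str,
    *,
    phenotype_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
    recode_pheno_12: bool = False,
) -> GenotypeDataset:
    """Convert an external layout into a validated dataset.

    Value-preserving: genotype scores are taken at face value (assumed to
    already count minor alleles); only the phenotype may be remapped, and
    only when ``recode_pheno_12`` is set.
    """
    return read_dataset(
        path,
        dialect=source_dialect,
        phenotype_path=phenotype_path,
        annotation_path=annotation_path,
        recode_pheno_12=recode_pheno_12,
    )


def write_dataset(data: GenotypeDataset, path: str | Path) -> None:
    """Write *data* in the canonical dialect; ``read_dataset`` inverts it exactly."""
    data.validate()
    tokens = {0: "0", 1: "1", 2: "2", MISSING: MISSING_TOKEN}
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(["PHENO", *data.snp_ids]) + "\n")
        for i in range(data.n_individuals):
            row = [str(int(data.phenotype[i]))]
            row.extend(tokens[int(g)] for g in data.genotypes[i])
            fh.write("\t".join(row) + "\n")


def read_annotations(path: str | Path) -> dict[str, str]:
    """Read a SNP_ID -> GENE mapping from a side-car annotation file."""
    mapping: dict[str, str] = {}
    for line_no, row in enumerate(_read_lines(path), start=1):
        if line_no == 1 and row[:2] == ["SNP_ID", "GENE"]:
            continue
        if len(row) < 2:
            raise DatasetFormatError(
                f"{path}: line {line_no}: expected SNP_ID<TAB>GENE"
            )
        mapping[row[0]] = row[1]
    return mapping


def write_annotations(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("SNP_ID\tGENE\n")
        for snp, gene in mapping.items():
            fh.write(f"{snp}\t{gene}\n")


# ---------------------------------------------------------------------------
# minor-allele frequency
# ---------------------------------------------------------------------------


def compute_maf(genotype_column: np.ndarray) -> float:
    """Minor-allele frequency of one additive genotype column.

    Missing entries are excluded from both the allele count and the
    denominator. The frequency is folded, ``min(p, 1 - p)``, so the result
    lies in [0, 0.5] regardless of which allele the scores count.
    """
    col = np.asarray(genotype_column)
    observed = col[col != MISSING]
    if observed.size == 0:
        raise UndefinedMAFError("MAF undefined: all genotypes missing")
    p = float(observed.sum()) / (2.0 * observed.size)
    return min(p, 1.0 - p)


def compute_mafs(data: GenotypeDataset) -> np.ndarray:
    """Per-SNP MAFs over all individuals (cases and controls pooled)."""
    out = np.empty(data.n_snps, dtype=float)
    for j in range(data.n_snps):
        out[j] = compute_maf(data.genotypes[:, j])
    return out


def filter_by_maf(data: GenotypeDataset, threshold: float) -> GenotypeDataset:
    """Keep exactly the SNPs with MAF strictly greater than *threshold*.

    SNP order and individuals are unchanged; an empty result is legal.
    All-missing columns have no defined MAF and are dropped.
    """
    if not 0 <= threshold < 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5), got {threshold}")
    keep = []
    for j in range(data.n_snps):
        try:
            if compute_maf(data.genotypes[:, j]) > threshold:
                keep.append(j)
        except UndefinedMAFError:
            continue
    return GenotypeDataset(
        data.phenotype.copy(),
        data.genotypes[:, keep].copy(),
        [data.snp_ids[j] for j in keep],
        [data.gene_names[j] for j in keep] if data.gene_names else [],
    )
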