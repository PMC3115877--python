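"""Fragment-tiled enumeration and execution of the all-pairs interaction scan.

The SNP axis is partitioned into non-overlapping fragments of S SNPs each
(the last fragment is conceptually padded up to S; padding is bookkeeping
only and can never emit a pair). Every unordered SNP pair is then visited
exactly once: k(k-1)/2 pairs within each fragment and k_i * k_j pairs across
each fragment pair i < j. Each block of pairs is an independent batch — a
pure function of the data and the pair list — so blocks can run on any
number of workers while the merged, canonically ordered output is identical
to a serial run.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import warnings
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from . import interaction
from .genotype_io import GenotypeDataset, compute_mafs, filter_by_maf
from .interaction import STATUS_CONVERGED, InteractionResult, lrt_pair

logger = logging.getLogger(__name__)

#: Fragment size used by default; matches the size the original study ran with.
DEFAULT_FRAGMENT_SIZE = 256

#: Hardware-era recommendation for S: a nonzero multiple of 32, at most 512.
#: Violations warn (results are unaffected by S) rather than error.
RECOMMENDED_MULTIPLE = 32
RECOMMENDED_MAX = 512

OUTPUT_HEADER = ("GENE1", "GENE2", "SNP1", "SNP2", "N_USED", "MAF1", "MAF2", "CHISQ", "P")


class FragmentSizeWarning(UserWarning):
    """The chosen fragment size is outside the recommended set."""


@dataclasses.dataclass(frozen=True)
class Fragment:
    """One fragment: global SNP indices ``start <= idx < stop`` are real."""

    start: int
    stop: int

    @property
    def n_real(self) -> int:
        return self.stop - self.start


@dataclasses.dataclass(frozen=True)
class FragmentPlan:
    """Partition of ``n_snps`` SNPs into fragments of size S (last one padded)."""

    S: int
    n_snps: int
    fragments: tuple[Fragment, ...]

    @property
    def F(self) -> int:
        return len(self.fragments)

    @property
    def n_padded(self) -> int:
        return self.F * self.S - self.n_snps

    def total_pairs(self) -> int:
        """Total unordered pairs enumerated by the plan, by block arithmetic.

        Sums k(k-1)/2 over fragments plus k_i*k_j over fragment pairs i < j,
        without materializing any pair list; equals n_snps*(n_snps-1)/2.
        """
        ks = [f.n_real for f in self.fragments]
        within = sum(k * (k - 1) // 2 for k in ks)
        total = sum(ks)
        across = (total * total - sum(k * k for k in ks)) // 2
        return within + across


def plan_fragments(n_snps: int, S: int) -> FragmentPlan:
    """Partition ``n_snps`` SNPs into ceil(n_snps/S) fragments of size S.

    Every fragment except possibly the last holds exactly S real SNPs; the
    last holds the remainder and is padded (as bookkeeping) up to S. A
    fragment size that is not a positive multiple of 32, or exceeds 512,
    triggers a :class:`FragmentSizeWarning` but is accepted.
    """
    if n_snps < 1:
        raise ValueError(f"n_snps must be >= 1, got {n_snps}")
    if S < 1:
        raise ValueError(f"fragment size must be >= 1, got {S}")
    if S % RECOMMENDED_MULTIPLE != 0 or S > RECOMMENDED_MAX:
        warnings.warn(
            f"fragment size {S} is outside the recommended set (nonzero "
            f"multiples of {RECOMMENDED_MULTIPLE} up to {RECOMMENDED_MAX}); "
            "results are unaffected",
            FragmentSizeWarning,
            stacklevel=2,
        )
    frags = tuple(
        Fragment(start, min(start + S, n_snps)) for start in range(0, n_snps, S)
    )
    return FragmentPlan(S=S, n_snps=n_snps, fragments=frags)


def pairs_within(plan: FragmentPlan, i: int) -> np.ndarray:
    """All unordered pairs (a, b), a < b, of real SNPs inside fragment *i*.

    Lexicographic order; k(k-1)/2 rows for k real SNPs; padded slots never
    appear. Returns an (n_pairs, 2) array of global SNP indices.
    """
    frag = plan.fragments[i]
    idx = np.arange(frag.start, frag.stop)
    a, b = np.triu_indices(frag.n_real, k=1)
    return np.column_stack((idx[a], idx[b]))


def pairs_across(plan: FragmentPlan, i: int, j: int) -> np.ndarray:
    """Cartesian product of fragment *i*'s and fragment *j*'s real SNPs.

    Requires i < j so each cross block is visited once; row-major order,
    k_i * k_j rows; padding excluded.
    """
    if i >= j:
        raise ValueError(f"cross blocks require i < j, got i={i}, j={j}")
    fi, fj = plan.fragments[i], plan.fragments[j]
    ai = np.repeat(np.arange(fi.start, fi.stop), fj.n_real)
    bj = np.tile(np.arange(fj.start, fj.stop), fi.n_real)
    return np.column_stack((ai, bj))


def iter_blocks(plan: FragmentPlan):
    """Yield (i, j) block coordinates in canonical order; j == i means within."""
    for i in range(plan.F):
        yield (i, i)
        for j in range(i + 1, plan.F):
            yield (i, j)


# ---------------------------------------------------------------------------
# scan configuration and execution
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ScanConfig:
    """Settings for one all-pairs scan.

    Defaults mirror the original study's run: fragment size 256, MAF filter
    at 0.15 (strict), output threshold p <= 0.001.
    """

    S: int = DEFAULT_FRAGMENT_SIZE
    maf_threshold: float = 0.15
    p_threshold: float = 0.001
    tol: float = interaction.DEFAULT_TOL
    max_iter: int = interaction.DEFAULT_MAX_ITER
    workers: int = 1
    output: str | None = None
    flush_interval: int = 100_000
    max_individuals: int | None = None  # soft memory guard; None = unlimited
    seed: int = 0

    def validate(self) -> None:
        if self.S < 1:
            raise ValueError("fragment size S must be >= 1")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")
        if not 0 <= self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5)")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.flush_interval < 1:
            raise ValueError("flush_interval must be >= 1")


@dataclasses.dataclass
class ScanSummary:
    """Run totals; pairs_tested = passing + failing_threshold + non_converged."""

    n_individuals: int = 0
    snps_input: int = 0
    snps_after_maf: int = 0
    fragments: int = 0
    pairs_tested: int = 0
    pairs_passing: int = 0
    pairs_failing_threshold: int = 0
    pairs_non_converged: int = 0

    def as_text(self, config: ScanConfig) -> str:
        lines = ["# scan summary"]
        for field in dataclasses.fields(ScanConfig):
            lines.append(f"config.{field.name} = {getattr(config, field.name)}")
        for field in dataclasses.fields(ScanSummary):
            lines.append(f"{field.name} = {getattr(self, field.name)}")
        return "\n".join(lines) + "\n"


def _eval_pairs(
    genotypes: np.ndarray,
    y: np.ndarray,
    pairs: np.ndarray,
    tol: float,
    max_iter: int,
) -> list[tuple[int, int, float | None, float | None, int, str]]:
    """Test every pair in one block; pure function of its arguments."""
    out = []
    for a, b in pairs:
        res = lrt_pair(
            genotypes[:, a], genotypes[:, b], y, tol=tol, max_iter=max_iter
        )
        out.append((int(a), int(b), res.lrt_stat, res.p_value, res.n_used, res.status))
    return out


def _format_row(
    data: GenotypeDataset,
    mafs: np.ndarray,
    row: tuple[int, int, float | None, float | None, int, str],
) -> str:
    a, b, stat, p, n_used, _status = row
    return "\t".join(
        (
            data.gene_of(a) or ".",
            data.gene_of(b) or ".",
            data.snp_ids[a],
            data.snp_ids[b],
            str(n_used),
            f"{mafs[a]:.4f}",
            f"{mafs[b]:.4f}",
            f"{stat:.6f}",
            f"{p:.5e}",
        )
    )


def run_scan(
    data: GenotypeDataset, config: ScanConfig
) -> tuple[list[InteractionResult], ScanSummary]:
    """Exhaustive pairwise interaction scan over a dataset.

    Applies the MAF filter, plans fragments, evaluates the interaction LRT
    for every enumerated pair in independent batches, and returns the results
    with ``p_value <= p_threshold`` in canonical order (by first SNP index,
    then second), independent of worker count and fragment size. When
    ``config.output`` is set, results are also written as tab-delimited text;
    long scans checkpoint raw passing rows to ``<output>.partial`` every
    ``flush_interval`` tested pairs, and the marker is removed once the final
    sorted output is in place.
    """
    config.validate()
    if (
        config.max_individuals is not None
        and data.n_individuals > config.max_individuals
    ):
        raise ValueError(
            f"dataset has {data.n_individuals} individuals, exceeding the "
            f"configured guard of {config.max_individuals}"
        )
    summary = ScanSummary(
        n_individuals=data.n_individuals, snps_input=data.n_snps
    )
    filtered = filter_by_maf(data, config.maf_threshold)
    summary.snps_after_maf = filtered.n_snps
    if filtered.n_snps < 2:
        logger.info("fewer than 2 SNPs after MAF filter; nothing to test")
        if config.output:
            _write_output(config.output, filtered, np.empty(0), [])
        return [], summary

    mafs = compute_mafs(filtered)
    plan = plan_fragments(filtered.n_snps, config.S)
    summary.fragments = plan.F
    y = filtered.phenotype.astype(np.float64)
    geno = filtered.genotypes

    blocks = list(iter_blocks(plan))
    pair_lists = [
        pairs_within(plan, i) if i == j else pairs_across(plan, i, j)
        for i, j in blocks
    ]

    if config.workers == 1:
        block_results = [
            _eval_pairs(geno, y, pairs, config.tol, config.max_iter)
            for pairs in pair_lists
        ]
    else:
        block_results = Parallel(n_jobs=config.workers)(
            delayed(_eval_pairs)(geno, y, pairs, config.tol, config.max_iter)
            for pairs in pair_lists
        )

    passing: list[tuple[int, int, float | None, float | None, int, str]] = []
    partial_path = f"{config.output}.partial" if config.output else None
    flushed = 0
    since_flush = 0
    for (i, j), rows in zip(blocks, block_results):
        summary.pairs_tested += len(rows)
        since_flush += len(rows)
        for row in rows:
            if row[5] != STATUS_CONVERGED:
                summary.pairs_non_converged += 1
            elif row[3] is not None and row[3] <= config.p_threshold:
                passing.append(row)
            else:
                summary.pairs_failing_threshold += 1
        if i == j:
            logger.info("fragment %d/%d: within-block done", i + 1, plan.F)
        if partial_path and since_flush >= config.flush_interval:
            _flush_partial(partial_path, filtered, mafs, passing[flushed:])
            flushed = len(passing)
            since_flush = 0

    passing.sort(key=lambda r: (r[0], r[1]))
    summary.pairs_passing = len(passing)

    if config.output:
        _write_output(config.output, filtered, mafs, passing)
        if partial_path and os.path.exists(partial_path):
            os.remove(partial_path)

    results = [
        InteractionResult(
            snp1_id=filtered.snp_ids[a],
            snp2_id=filtered.snp_ids[b],
            gene1=filtered.gene_of(a),
            gene2=filtered.gene_of(b),
            lrt_stat=stat,
            p_value=p,
            maf1=float(mafs[a]),
            maf2=float(mafs[b]),
            n_used=n_used,
            status=status,
        )
        for a, b, stat, p, n_used, status in passing
    ]
    return results, summary


def _flush_partial(path, data, mafs, rows) -> None:
    with open(path, "a", newline="\n") as fh:
        for row in rows:
            fh.write(_format_row(data, mafs, row) + "\n")


def _write_output(path, data, mafs, rows) -> None:
    tmp = f"{path}.tmp"
    try:
        with open(tmp, "w", newline="\n") as fh:
            fh.write("\t".join(OUTPUT_HEADER) + "\n")
            for row in rows:
                fh.write(_format_row(data, mafs, row) + "\n")
        os.replace(tmp, path)
    except OSError:
        # leave a marker so a truncated run is never mistaken for a result
        Path(f"{path}.partial-error").touch(exist_ok=True)
        raise


def scan_invariance_check(
    data: GenotypeDataset, S_a: int, S_b: int, *, maf_threshold: float = 0.0
) -> bool:
    """True iff scans at fragment sizes S_a and S_b produce identical results.

    Runs both scans with p_threshold = 1 so every tested pair is compared:
    the pair set, LRT statistics and p-values must match exactly.
    """
    res_a, _ = run_scan(
        data, ScanConfig(S=S_a, maf_threshold=maf_threshold, p_threshold=1.0)
    )
    res_b, _ = run_scan(
        data, ScanConfig(S=S_b, maf_threshold=maf_threshold, p_threshold=1.0)
    )
    key = lambda r: (r.snp1_id, r.snp2_id, r.lrt_stat, r.p_value, r.n_used, r.status)
    return len(res_a) == len(res_b) and all(
        key(x) == key(y) for x, y in zip(res_a, res_b)
    )
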