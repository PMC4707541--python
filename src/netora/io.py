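"""Readers and writers for the package's plain-text formats.

Formats: tab-separated edge lists (``geneA geneB [weight]``), GMT gene-set
collections, newline-delimited gene lists, TSV result tables and TSV
module tables.  Writers and readers round-trip: writing a structure and
reading it back reproduces it exactly.  Malformed lines raise errors
naming the file, line number and offending content; unknown or dropped
genes are reported as counts, never silently.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .enrichment import EnrichmentResult, InterestingGeneList
from .network import GeneNetwork
from .redundancy import FilteredResults, ModulePartition
from .weighting import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "read_network",
    "read_genesets",
    "read_gene_list",
    "write_results",
    "read_results",
    "write_modules",
    "write_module_report",
]

RESULT_COLUMNS = (
    "set_name",
    "k",
    "n_used",
    "ES_obs",
    "p_empirical",
    "p_gpd",
    "p_final",
    "p_bonferroni",
    "p_bh_fdr",
    "rank",
)


def _fold(name: str, case_fold: bool) -> str:
    name = name.strip()
    return name.lower() if case_fold else name


def read_network(path: str | Path, case_fold: bool = False) -> GeneNetwork:
    """Read a TSV edge list (2 or 3 columns; '#' lines skipped).

    A missing weight column means an unweighted network (all weights 1,
    logged once).  Gene order follows first appearance.
    """
    path = Path(path)
    genes: dict[str, None] = {}
    edges: list[tuple[str, str, float]] = []
    saw_missing_weight = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, "
                    f"got {len(parts)}: {line!r}"
                )
            a, b = _fold(parts[0], case_fold), _fold(parts[1], case_fold)
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty gene identifier: {line!r}")
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric edge weight: {line!r}"
                    ) from None
            else:
                w = 1.0
                saw_missing_weight = True
            genes.setdefault(a)
            genes.setdefault(b)
            edges.append((a, b, w))
    if saw_missing_weight:
        logger.info("%s: no weight column; treating the network as unweighted", path)
    return GeneNetwork(tuple(genes), edges)


def read_genesets(path: str | Path, case_fold: bool = False) -> GeneSetCollection:
    """Read a GMT file: name, description, then member genes, tab-separated.

    Blank and duplicate members are dropped with a warning.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and at "
                    f"least one gene: {line!r}"
                )
            name, description = parts[0].strip(), parts[1]
            members: dict[str, None] = {}
            n_dupes = 0
            for raw in parts[2:]:
                g = _fold(raw, case_fold)
                if not g:
                    continue
                if g in members:
                    n_dupes += 1
                members.setdefault(g)
            if n_dupes:
                logger.warning(
                    "%s:%d: gene set %r has %d duplicate member(s)",
                    path, lineno, name, n_dupes,
                )
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name=name, members=frozenset(members), description=description))
    return GeneSetCollection(sets)


def read_gene_list(path: str | Path, case_fold: bool = False) -> InterestingGeneList:
    """Read a newline-delimited gene list; '#' lines skipped."""
    path = Path(path)
    ids: list[str] = []
    with path.open() as fh:
        for line in fh:
            g = _fold(line, case_fold)
            if g and not g.startswith("#"):
                ids.append(g)
    if not ids:
        raise ValueError(f"{path}: gene list is empty")
    return InterestingGeneList(ids)


def write_results(results: list[EnrichmentResult], path: str | Path) -> None:
    """Write the enrichment result table as TSV ('.' marks an absent GPD p)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            p_gpd = "." if r.p_gpd is None else repr(r.p_gpd)
            fh.write(
                "\t".join(
                    [
                        r.set_name,
                        str(r.k),
                        str(r.n_used),
                        repr(r.ES_obs),
                        repr(r.p_empirical),
                        p_gpd,
                        repr(r.p_final),
                        repr(r.p_bonferroni),
                        repr(r.p_bh_fdr),
                        str(r.rank),
                    ]
                )
                + "\n"
            )


def read_results(path: str | Path) -> list[EnrichmentResult]:
    """Read back a result table written by :func:`write_results`."""
    path = Path(path)
    results: list[EnrichmentResult] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != RESULT_COLUMNS:
            raise ValueError(f"{path}: unexpected result header: {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(RESULT_COLUMNS):
                raise ValueError(f"{path}:{lineno}: malformed result row: {line!r}")
            results.append(
                EnrichmentResult(
                    set_name=parts[0],
                    k=int(parts[1]),
                    n_used=int(parts[2]),
                    ES_obs=float(parts[3]),
                    N_perm=0,
                    p_empirical=float(parts[4]),
                    p_gpd=None if parts[5] == "." else float(parts[5]),
                    p_final=float(parts[6]),
                    p_bonferroni=float(parts[7]),
                    p_bh_fdr=float(parts[8]),
                    rank=int(parts[9]),
                )
            )
    return results


def write_modules(
    filtered: FilteredResults, partition: ModulePartition, path: str | Path
) -> None:
    """Write the module table: set_name, module_id, is_marker, p_final."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("set_name\tmodule_id\tis_marker\tp_final\n")
        for mod in filtered.modules:
            for r, marker in [(mod.marker, 1)] + [(o, 0) for o in mod.others]:
                fh.write(f"{r.set_name}\t{mod.module_id}\t{marker}\t{r.p_final!r}\n")


def write_module_report(filtered: FilteredResults, path: str | Path) -> None:
    """Human-readable grouped report: marker line, indented members."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# {len(filtered.modules)} module(s) at significance "
            f"{filtered.significance}\n"
        )
        for mod in filtered.modules:
            fh.write(
                f"module {mod.module_id}\t{mod.marker.set_name}\t"
                f"p={mod.marker.p_final:.3g}\n"
            )
            for other in mod.others:
                fh.write(f"    {other.set_name}\tp={other.p_final:.3g}\n")
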