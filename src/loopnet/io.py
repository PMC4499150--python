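"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV; genomic intervals use BED/BEDPE conventions (0-based
half-open).  Readers reject malformed input rather than coercing it;
writers emit sorted rows so runs are diffable.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .datatypes import (
    BindingEvent,
    Element,
    ExpressionData,
    Gene,
    GeneNetwork,
    PriorEdge,
    PriorTable,
    RegulatoryLandscape,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_regions",
    "write_landscape",
    "read_landscape",
    "read_network",
    "write_network",
    "read_prior_table",
    "write_prior_table",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def read_expression(path) -> ExpressionData:
    """Gene-by-sample TSV with a header row of sample ids.

    Duplicate gene ids and missing/non-numeric cells are rejected (the
    scoring model assumes complete data).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene rows: {', '.join(map(str, dups))}")
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression cell: {exc}") from exc
    return ExpressionData(df.index.astype(str), df.columns.astype(str), values)


def write_expression(expr: ExpressionData, path) -> None:
    df = pd.DataFrame(expr.values, index=list(expr.genes), columns=list(expr.samples))
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Regions / landscape
# ---------------------------------------------------------------------------


def _check_coords(chrom: str, start: int, end: int, where: str) -> None:
    if start < 0 or end < 0:
        raise ValueError(f"{where}: negative coordinate ({chrom}:{start}-{end})")
    if start >= end:
        raise ValueError(f"{where}: start must be < end ({chrom}:{start}-{end})")


def read_regions(path, kind: str):
    """Read landscape fragments.

    ``kind='genes'``: BED6-like TSV (chrom, tss_start, tss_end, name,
    score, strand) where the interval is the 1-bp TSS.  ``kind='elements'``:
    BED4 plus a kind column and a gene column (gene set for PREs, '.' for
    DREs).  ``kind='loops'``: BEDPE with anchor element names in columns 7
    and 8.
    """
    if kind == "genes":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "score", "strand"])
        genes = []
        for row in df.itertuples():
            _check_coords(row.chrom, int(row.start), int(row.end), f"gene {row.name}")
            genes.append(Gene(str(row.name), str(row.chrom), str(row.strand), int(row.start)))
        return genes
    if kind == "elements":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "kind", "gene"])
        elements, pre_gene = [], {}
        for row in df.itertuples():
            _check_coords(row.chrom, int(row.start), int(row.end), f"element {row.name}")
            elements.append(Element(str(row.name), str(row.kind), str(row.chrom),
                                    int(row.start), int(row.end)))
            if str(row.gene) != ".":
                pre_gene[str(row.name)] = str(row.gene)
        return elements, pre_gene
    if kind == "loops":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                                "anchor1", "anchor2"])
        loops = []
        for row in df.itertuples():
            _check_coords(row.chrom1, int(row.start1), int(row.end1), "loop anchor 1")
            _check_coords(row.chrom2, int(row.start2), int(row.end2), "loop anchor 2")
            loops.append((str(row.anchor1), str(row.anchor2)))
        return loops
    raise ValueError(f"unknown region kind {kind!r}")


def write_landscape(landscape: RegulatoryLandscape, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = sorted(landscape.genes.values(), key=lambda g: g.name)
    with open(outdir / "genes.bed", "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.name}\t0\t{g.strand}\n")
    elements = sorted(landscape.elements.values(), key=lambda e: e.name)
    with open(outdir / "elements.bed", "w") as fh:
        for e in elements:
            gene = landscape.pre_gene.get(e.name, ".")
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.name}\t{e.kind}\t{gene}\n")
    with open(outdir / "loops.bedpe", "w") as fh:
        for a, b in sorted(landscape.loops):
            ea, eb = landscape.elements[a], landscape.elements[b]
            fh.write(
                f"{ea.chrom}\t{ea.start}\t{ea.end}\t{eb.chrom}\t{eb.start}\t{eb.end}\t{a}\t{b}\n"
            )
    events = sorted(
        landscape.binding_events,
        key=lambda ev: (ev.tf, ev.element, ev.evidence, ev.cell_context, ev.accessible),
    )
    with open(outdir / "binding_events.tsv", "w") as fh:
        fh.write("tf\telement_id\tevidence\tcell_context\taccessible\n")
        for ev in events:
            fh.write(
                f"{ev.tf}\t{ev.element}\t{ev.evidence}\t{ev.cell_context}\t{int(ev.accessible)}\n"
            )
    if landscape.chrom_sizes:
        with open(outdir / "chrom.sizes", "w") as fh:
            for c in sorted(landscape.chrom_sizes):
                fh.write(f"{c}\t{landscape.chrom_sizes[c]}\n")


def read_landscape(indir) -> RegulatoryLandscape:
    indir = Path(indir)
    genes = read_regions(indir / "genes.bed", "genes")
    elements, pre_gene = read_regions(indir / "elements.bed", "elements")
    loops = read_regions(indir / "loops.bedpe", "loops")
    ev = pd.read_csv(indir / "binding_events.tsv", sep="\t")
    events = [
        BindingEvent(str(r.tf), str(r.element_id), str(r.evidence), str(r.cell_context),
                     bool(r.accessible))
        for r in ev.itertuples()
    ]
    sizes = {}
    sizes_path = indir / "chrom.sizes"
    if sizes_path.exists():
        for line in sizes_path.read_text().splitlines():
            c, s = line.split("\t")
            sizes[c] = int(s)
    return RegulatoryLandscape(genes, elements, pre_gene, loops, events, sizes)


# ---------------------------------------------------------------------------
# Networks and priors
# ---------------------------------------------------------------------------


def write_network(network: GeneNetwork, path) -> None:
    """Edge-list TSV: regulator, target, sign, support (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tsign\tsupport\n")
        for u, v in sorted(network.edges):
            sign = network.signs.get((u, v), "")
            support = network.support.get((u, v), "")
            fh.write(f"{u}\t{v}\t{sign}\t{support}\n")
    nodes_path = Path(path).with_suffix(Path(path).suffix + ".nodes")
    nodes_path.write_text("\n".join(network.nodes) + ("\n" if network.nodes else ""))


def read_network(path, allow_self_loops: bool = False) -> GeneNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    nodes_path = Path(path).with_suffix(Path(path).suffix + ".nodes")
    if nodes_path.exists():
        nodes = [l for l in nodes_path.read_text().splitlines() if l]
    else:
        nodes = sorted(set(df["regulator"]) | set(df["target"]))
    edges, signs, support = [], {}, {}
    for row in df.itertuples():
        if row.regulator == row.target and not allow_self_loops:
            raise ValueError(f"self-loop row on {row.regulator!r}")
        e = (row.regulator, row.target)
        edges.append(e)
        if "sign" in df.columns and pd.notna(row.sign) and str(row.sign) != "":
            signs[e] = int(row.sign)
        if "support" in df.columns and pd.notna(row.support) and str(row.support) != "":
            support[e] = int(row.support)
    return GeneNetwork(nodes, edges, signs, support)


def write_prior_table(table: PriorTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tprobability\tevidence\tcell_context\ttopology\n")
        for key in sorted(table.entries):
            e = table.entries[key]
            if isinstance(e.cls, str):
                ev = ctx = topo = e.cls
            else:
                ev, ctx, topo = e.cls
            fh.write(f"{e.regulator}\t{e.target}\t{e.probability:.6g}\t{ev}\t{ctx}\t{topo}\n")


def read_prior_table(path) -> PriorTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    table = PriorTable()
    for row in df.itertuples():
        if row.evidence == row.cell_context == row.topology:
            cls = row.evidence  # string marker class (e.g. "eqtl")
        else:
            cls = (row.evidence, row.cell_context, row.topology)
        table.add(PriorEdge(row.regulator, row.target, float(row.probability), cls))
    return table


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


class RunConfig:
    """Structured YAML configuration for the CLI subcommands.

    Known top-level keys: ``seed``, ``outdir``, ``log_level`` and one
    section per subcommand (``simulate``, ``priors``, ``learn``,
    ``evaluate``, ``analyze``).  Unknown keys are rejected.  The fully
    resolved configuration is written next to each run's outputs.
    """

    SECTIONS = ("simulate", "priors", "learn", "evaluate", "analyze")
    GLOBALS = ("seed", "outdir", "log_level")

    def __init__(self, mapping: dict | None = None):
        mapping = dict(mapping or {})
        unknown = set(mapping) - set(self.SECTIONS) - set(self.GLOBALS)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        self.seed = int(mapping.get("seed", 0))
        self.outdir = mapping.get("outdir", ".")
        self.log_level = mapping.get("log_level", "INFO")
        for s in self.SECTIONS:
            section = mapping.get(s, {}) or {}
            if not isinstance(section, dict):
                raise ValueError(f"config section {s!r} must be a mapping")
            setattr(self, s, section)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def resolved(self) -> dict:
        out = {"seed": self.seed, "outdir": str(self.outdir), "log_level": self.log_level}
        for s in self.SECTIONS:
            out[s] = getattr(self, s)
        return out

    def write_resolved(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=True)
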