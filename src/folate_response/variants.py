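"""Panel-restricted germline variant pipeline.

Consumes MAF-like per-patient variant tables produced upstream of this
package (alignment, calling and annotation are out of scope), restricts
them to a one-carbon-metabolism gene panel (BED), splits them into
ClinVar-annotated ("classified") and unknown ("unclassified") sets,
computes per-group carrier frequencies, applies the dual-threshold hotspot
rule (>= 70% of non-responders AND < 50% of responders), summarizes
mutation spectra, and exports the pathway-gene-mutation bipartite graph.

Coordinate conventions: MAF positions are 1-based inclusive; BED regions
are 0-based half-open. A 1-based position ``p`` falls in region
``[start, end)`` iff ``start < p <= end``.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

from .stratification import NON_RESPONDER, RESPONDER

#: MAF Variant_Classification strings -> internal categories
CLASSIFICATION_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Del": "frame_shift_del",
    "Frame_Shift_Ins": "frame_shift_ins",
    "In_Frame_Del": "in_frame_del",
    "In_Frame_Ins": "in_frame_ins",
    "Splice_Site": "splice_site",
    "Silent": "silent",
    # noncoding/regulatory calls collapse into the catch-all category
    "3'UTR": "other",
    "5'UTR": "other",
    "Intron": "other",
    "Targeted_Region": "other",
}
MAF_CLASSIFICATION = {
    v: k for k, v in CLASSIFICATION_MAP.items() if v != "other"
} | {"other": "Targeted_Region"}

#: the six canonical SNV classes (reference collapsed to the pyrimidine)
SNV_CLASSES = ("C>T", "T>C", "C>G", "C>A", "T>A", "T>G")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

REQUIRED_MAF_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
)


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one patient.

    ``variant_key`` is the normalized ``chrom:pos:ref:alt`` identity
    (1-based position); ``hgvs_label`` is an opaque display string.
    """

    patient_id: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_classification: str
    variant_type: str  # SNP | DEL | INS
    hgvs_label: str = ""
    zygosity: str = "unknown"

    def __post_init__(self):
        if self.pos <= 0:
            raise ValueError("variant position must be positive (1-based)")

    @property
    def variant_key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def snv_class(self) -> str | None:
        """Pyrimidine-reference SNV class; None for non-SNPs."""
        if self.variant_type != "SNP":
            return None
        ref, alt = self.ref.upper(), self.alt.upper()
        if ref in ("A", "G"):
            ref, alt = _COMPLEMENT.get(ref, ref), _COMPLEMENT.get(alt, alt)
        label = f"{ref}>{alt}"
        return label if label in SNV_CLASSES else None


@dataclass(frozen=True)
class PanelRegion:
    """One gene interval of the panel BED (0-based half-open)."""

    chrom: str
    start: int
    end: int
    gene: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty panel region for {self.gene}")


@dataclass
class HotspotCall:
    """Per-group carrier frequencies for one variant, with the rule flags."""

    variant_key: str
    gene: str
    hgvs_label: str
    pathway: str
    carriers_responder: int
    carriers_nonresponder: int
    size_responder: int
    size_nonresponder: int
    is_graph_node: bool = False
    is_highlighted: bool = False

    @property
    def freq_responder(self) -> float:
        return round(100.0 * self.carriers_responder / self.size_responder, 2)

    @property
    def freq_nonresponder(self) -> float:
        return round(100.0 * self.carriers_nonresponder / self.size_nonresponder, 2)


def _infer_variant_type(ref: str, alt: str, declared: str | None = None) -> str:
    if declared in ("SNP", "DEL", "INS"):
        return declared
    if len(ref) == 1 and len(alt) == 1 and ref != "-" and alt != "-":
        return "SNP"
    if len(ref) > len(alt) or alt == "-":
        return "DEL"
    return "INS"


def read_variants(maf_path) -> list[VariantRecord]:
    """Read a MAF-like TSV into normalized variant records.

    The tumor-centric MAF column names are accepted but reinterpreted for
    germline calls (``Tumor_Sample_Barcode`` is the patient id). Unknown
    classification strings map to ``other`` with a warning.
    """
    df = pd.read_csv(maf_path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file is missing mandatory column(s): {missing}")
    records = []
    unknown = Counter()
    for row in df.itertuples():
        cls = CLASSIFICATION_MAP.get(row.Variant_Classification)
        if cls is None:
            unknown[row.Variant_Classification] += 1
            cls = "other"
        vtype = _infer_variant_type(
            row.Reference_Allele, row.Tumor_Seq_Allele2, getattr(row, "Variant_Type", None)
        )
        records.append(
            VariantRecord(
                patient_id=row.Tumor_Sample_Barcode,
                gene=row.Hugo_Symbol,
                chrom=str(row.Chromosome),
                pos=int(row.Start_Position),
                ref=row.Reference_Allele,
                alt=row.Tumor_Seq_Allele2,
                variant_classification=cls,
                variant_type=vtype,
                hgvs_label=getattr(row, "HGVSc", "") or "",
                zygosity=getattr(row, "Zygosity", "unknown") or "unknown",
            )
        )
    if unknown:
        warnings.warn(f"unknown variant classifications mapped to 'other': {dict(unknown)}")
    return records


def write_variants(records: list[VariantRecord], path) -> None:
    """Write records back to a MAF-like TSV (inverse of :func:`read_variants`)."""
    rows = [
        {
            "Hugo_Symbol": r.gene,
            "Chromosome": r.chrom,
            "Start_Position": r.pos,
            "End_Position": r.pos + max(len(r.ref.strip("-")) - 1, 0),
            "Reference_Allele": r.ref,
            "Tumor_Seq_Allele2": r.alt,
            "Variant_Classification": MAF_CLASSIFICATION.get(
                r.variant_classification, "Targeted_Region"
            ),
            "Variant_Type": r.variant_type,
            "Tumor_Sample_Barcode": r.patient_id,
            "HGVSc": r.hgvs_label,
            "Zygosity": r.zygosity,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel(bed_path) -> list[PanelRegion]:
    """Read a 3+1-column BED gene panel (0-based half-open)."""
    regions = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"panel BED needs 4 columns, got: {line!r}")
            regions.append(
                PanelRegion(parts[0], int(parts[1]), int(parts[2]), parts[3])
            )
    return regions


def restrict_to_panel(
    variants: list[VariantRecord], regions: list[PanelRegion]
) -> list[VariantRecord]:
    """Keep variants whose 1-based position lies in some panel region."""
    if not regions:
        raise ValueError("panel region list is empty")
    by_chrom = defaultdict(list)
    for reg in regions:
        by_chrom[reg.chrom].append(reg)
    kept = []
    for v in variants:
        for reg in by_chrom.get(v.chrom, ()):
            if reg.start < v.pos <= reg.end:  # BED half-open vs MAF 1-based
                kept.append(v)
                break
    return kept


def read_annotation(path) -> dict[str, str]:
    """Load a ClinVar-style ``variant_key -> clinical_significance`` TSV.

    Malformed rows are skipped; their count is warned about once.
    """
    db: dict[str, str] = {}
    skipped = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("variant_key"):
            raise ValueError("annotation TSV must start with a variant_key header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0] or parts[0].count(":") != 3:
                skipped += 1
                continue
            db[parts[0]] = parts[1]
    if skipped:
        warnings.warn(f"skipped {skipped} malformed annotation row(s)")
    return db


def classify_by_annotation(
    variants: list[VariantRecord], db: dict[str, str]
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split variants into annotated ("classified") and unknown sets.

    A variant is classified iff its key is in the database with a non-empty
    clinical-significance string (any string qualifies, including
    "Uncertain significance"); both lists are preserved.
    """
    classified, unclassified = [], []
    for v in variants:
        if db.get(v.variant_key):
            classified.append(v)
        else:
            unclassified.append(v)
    return classified, unclassified


def _group_ids(labels: pd.DataFrame) -> dict[str, set]:
    return {
        RESPONDER: set(labels.loc[labels["label"] == RESPONDER, "patient_id"]),
        NON_RESPONDER: set(labels.loc[labels["label"] == NON_RESPONDER, "patient_id"]),
    }


def carrier_frequency(
    variants: list[VariantRecord], labels: pd.DataFrame, variant_key: str
) -> dict[str, tuple[int, int, float]]:
    """Per-group (carriers, group size, percent) for one variant.

    A patient counts once regardless of zygosity or record multiplicity;
    percent is rounded to two decimals.
    """
    groups = _group_ids(labels)
    known = groups[RESPONDER] | groups[NON_RESPONDER]
    carriers = {RESPONDER: set(), NON_RESPONDER: set()}
    for v in variants:
        if v.variant_key != variant_key:
            continue
        if v.patient_id not in known:
            raise ValueError(f"variant carrier {v.patient_id!r} is not a labeled patient")
        for group, ids in groups.items():
            if v.patient_id in ids:
                carriers[group].add(v.patient_id)
    out = {}
    for group, ids in groups.items():
        size = len(ids)
        if size == 0:
            raise ValueError(f"group {group} is empty")
        n = len(carriers[group])
        out[group] = (n, size, round(100.0 * n / size, 2))
    return out


def compute_frequencies(
    variants: list[VariantRecord],
    labels: pd.DataFrame,
    pathway_map: dict[str, list[str]] | None = None,
) -> list[HotspotCall]:
    """Carrier frequencies for every distinct variant key, one call each."""
    groups = _group_ids(labels)
    known = groups[RESPONDER] | groups[NON_RESPONDER]
    carriers: dict[str, dict[str, set]] = defaultdict(
        lambda: {RESPONDER: set(), NON_RESPONDER: set()}
    )
    meta: dict[str, VariantRecord] = {}
    for v in variants:
        if v.patient_id not in known:
            raise ValueError(f"variant carrier {v.patient_id!r} is not a labeled patient")
        meta.setdefault(v.variant_key, v)
        for group, ids in groups.items():
            if v.patient_id in ids:
                carriers[v.variant_key][group].add(v.patient_id)
    calls = []
    for key in sorted(carriers):
        v = meta[key]
        pathways = (pathway_map or {}).get(v.gene, [])
        calls.append(
            HotspotCall(
                variant_key=key,
                gene=v.gene,
                hgvs_label=v.hgvs_label,
                pathway=";".join(pathways),
                carriers_responder=len(carriers[key][RESPONDER]),
                carriers_nonresponder=len(carriers[key][NON_RESPONDER]),
                size_responder=len(groups[RESPONDER]),
                size_nonresponder=len(groups[NON_RESPONDER]),
            )
        )
    return calls


def call_hotspots(
    freqs: list[HotspotCall],
    node_threshold: float = 50.0,
    highlight_in: float = 70.0,
    highlight_out: float = 50.0,
) -> list[HotspotCall]:
    """Apply the dual-threshold hotspot rule.

    ``is_graph_node``: non-responder frequency >= ``node_threshold`` ("at
    least 50%"). ``is_highlighted``: non-responder frequency >=
    ``highlight_in`` AND responder frequency strictly < ``highlight_out``
    ("at least 70% ... less than 50%").
    """
    out = []
    for call in freqs:
        out.append(
            replace(
                call,
                is_graph_node=call.freq_nonresponder >= node_threshold,
                is_highlighted=(
                    call.freq_nonresponder >= highlight_in
                    and call.freq_responder < highlight_out
                ),
            )
        )
    return out


def hotspots_frame(calls: list[HotspotCall]) -> pd.DataFrame:
    """Tabular view of hotspot calls for TSV export."""
    return pd.DataFrame(
        [
            {
                "variant_key": c.variant_key,
                "gene": c.gene,
                "hgvs_label": c.hgvs_label,
                "pathway": c.pathway,
                "carriers_responder": c.carriers_responder,
                "size_responder": c.size_responder,
                "freq_responder": c.freq_responder,
                "carriers_nonresponder": c.carriers_nonresponder,
                "size_nonresponder": c.size_nonresponder,
                "freq_nonresponder": c.freq_nonresponder,
                "is_graph_node": c.is_graph_node,
                "is_highlighted": c.is_highlighted,
            }
            for c in calls
        ]
    )


@dataclass
class MutationSummary:
    """Counts underlying a maftools-style mutation summary."""

    classification_counts: dict[str, int]
    type_counts: dict[str, int]
    snv_class_counts: dict[str, int]
    gene_counts: dict[str, int]
    top_genes: list[str]
    per_patient_counts: dict[str, int]
    oncomatrix: pd.DataFrame  # gene x patient; classification, Multi_Hit or ""


def summarize_mutations(variants: list[VariantRecord], top_k: int = 10) -> MutationSummary:
    """Mutation spectrum, per-gene totals, top-k genes and the oncomatrix.

    Top-k ties are broken deterministically: count descending, then gene
    symbol ascending. An oncomatrix cell is ``Multi_Hit`` when a gene holds
    two or more variants in the same patient, otherwise the single
    variant's classification.
    """
    if not variants:
        raise ValueError("no variants to summarize")
    cls_counts = Counter(v.variant_classification for v in variants)
    type_counts = Counter(v.variant_type for v in variants)
    snv_counts = Counter(v.snv_class for v in variants if v.snv_class)
    gene_counts = Counter(v.gene for v in variants)
    patient_counts = Counter(v.patient_id for v in variants)
    top = sorted(gene_counts, key=lambda g: (-gene_counts[g], g))[:top_k]

    per_cell: dict[tuple[str, str], list[str]] = defaultdict(list)
    for v in variants:
        per_cell[(v.gene, v.patient_id)].append(v.variant_classification)
    genes = sorted(gene_counts)
    patients = sorted(patient_counts)
    matrix = pd.DataFrame("", index=genes, columns=patients)
    for (gene, pid), hits in per_cell.items():
        matrix.loc[gene, pid] = "Multi_Hit" if len(hits) >= 2 else hits[0]
    return MutationSummary(
        classification_counts=dict(cls_counts),
        type_counts=dict(type_counts),
        snv_class_counts=dict(snv_counts),
        gene_counts=dict(gene_counts),
        top_genes=top,
        per_patient_counts=dict(patient_counts),
        oncomatrix=matrix,
    )


UNMAPPED_PATHWAY = "unmapped"


def build_pathway_graph(
    hotspots: list[HotspotCall], pathway_map: dict[str, list[str]]
) -> nx.Graph:
    """Bipartite pathway / (gene, mutation) graph of the graph-node hotspots.

    Central nodes are pathways; peripheral nodes are gene-mutation pairs for
    every call with ``is_graph_node``. Edges carry a ``highlighted`` flag
    for calls passing the dual-threshold rule. Genes absent from the
    pathway map attach to a catch-all node with a warning.
    """
    graph = nx.Graph()
    nodes = [h for h in hotspots if h.is_graph_node]
    if not nodes:
        warnings.warn("no hotspot reaches the graph-node threshold; graph is empty")
    for call in nodes:
        label = call.hgvs_label or call.variant_key
        mut_node = f"{call.gene}:{label}"
        graph.add_node(
            mut_node,
            kind="mutation",
            gene=call.gene,
            variant_key=call.variant_key,
            freq_responder=call.freq_responder,
            freq_nonresponder=call.freq_nonresponder,
            highlighted=call.is_highlighted,
        )
        pathways = pathway_map.get(call.gene)
        if not pathways:
            warnings.warn(f"gene {call.gene} has no pathway mapping; using catch-all")
            pathways = [UNMAPPED_PATHWAY]
        for pw in pathways:
            if pw not in graph:
                graph.add_node(pw, kind="pathway")
            graph.add_edge(pw, mut_node, highlighted=call.is_highlighted)
    return graph


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_dot(graph: nx.Graph, path) -> None:
    """Minimal DOT export with node kinds and highlighted-edge styling."""
    def q(s: str) -> str:
        return '"' + str(s).replace('"', r"\"") + '"'

    with open(path, "w") as fh:
        fh.write("graph pathway_hotspots {\n")
        for node, data in sorted(graph.nodes(data=True)):
            shape = "ellipse" if data.get("kind") == "pathway" else "box"
            fh.write(f"  {q(node)} [shape={shape}];\n")
        for u, v, data in sorted(graph.edges(data=True)):
            style = ' [style=dashed, color=red]' if data.get("highlighted") else ""
            fh.write(f"  {q(u)} -- {q(v)}{style};\n")
        fh.write("}\n")
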