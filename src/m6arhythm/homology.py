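"""Ortholog/paralog network inference from all-vs-all similarity tables.

The inference follows the comparative-genomics recipe used to build m6A
writer/eraser gene-family inventories:

* cross-species **orthologs** are bidirectional best hits (BBH): two
  proteins in different species that are each other's best hit;
* within-species **paralogs** are reciprocally reported pairs whose better
  E-value passes a species-specific cutoff, where the cutoff is chosen
  from a grid as the one that **maximises the number of paralog networks**
  (connected components with >= 2 members) for that species;
* ortholog and paralog edges are merged and the connected components of
  the union graph are the homology networks (``NET_1``, ``NET_2``, ...);
* networks are annotated by transferring per-protein function labels and
  retained whenever at least one member carries a writer/eraser label.

Species tags are taken from the ID prefix up to the first underscore
unless an explicit species map is supplied. E-values of exactly 0.0 are
treated as 1e-180 for log-scale work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import edlib
import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: controlled vocabulary for the annotation transfer
WRITER_LABELS = frozenset({"MTA", "MTB", "FIP37", "VIRILIZER", "HAKAI"})
ERASER_LABELS = frozenset({"ALKBH9B", "ALKBH10B"})

EVALUE_FLOOR = 1e-180


class SimilarityHit(NamedTuple):
    query_id: str
    subject_id: str
    evalue: float
    bitscore: float


class SimilarityFormatError(ValueError):
    """Raised for malformed similarity-table rows (carries the line number)."""


@dataclass
class SimilarityTable:
    hits: list[SimilarityHit]
    n_self_dropped: int = 0

    def __iter__(self):
        return iter(self.hits)

    def __len__(self):
        return len(self.hits)


def species_of(protein_id: str, species_map: Optional[Mapping[str, str]] = None) -> str:
    """Species tag of a protein ID (prefix before the first underscore)."""
    if species_map is not None and protein_id in species_map:
        return species_map[protein_id]
    if "_" not in protein_id:
        raise ValueError(f"cannot derive species from protein id {protein_id!r}")
    return protein_id.split("_", 1)[0]


def read_similarity(path) -> SimilarityTable:
    """Parse an outfmt-6 TSV into similarity hits.

    Lines starting with ``#`` are ignored; self hits are dropped (counted
    in ``n_self_dropped``); rows with fewer than 12 columns or
    unparseable E-value/bitscore raise :class:`SimilarityFormatError`
    naming the offending line.
    """
    hits: list[SimilarityHit] = []
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise SimilarityFormatError(
                    f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            qid, sid = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise SimilarityFormatError(
                    f"line {lineno}: unparseable numeric field ({exc})"
                ) from None
            if qid == sid:
                n_self += 1
                continue
            hits.append(SimilarityHit(qid, sid, evalue, bitscore))
    return SimilarityTable(hits, n_self)


def _better(a: SimilarityHit, b: SimilarityHit) -> SimilarityHit:
    """Tie-break chain: E-value asc, bitscore desc, subject_id lexicographic."""
    ka = (a.evalue, -a.bitscore, a.subject_id)
    kb = (b.evalue, -b.bitscore, b.subject_id)
    return a if ka <= kb else b


def best_hit_map(
    hits: Iterable[SimilarityHit],
    scope: str = "cross_species",
    species_map: Optional[Mapping[str, str]] = None,
) -> dict[tuple[str, str], SimilarityHit]:
    """Best hit per (query, target species).

    ``scope`` restricts the candidate hits: ``"cross_species"`` keeps only
    hits whose subject is in another species, ``"within_species"`` the
    opposite.
    """
    if scope not in ("cross_species", "within_species"):
        raise ValueError(f"unknown scope {scope!r}")
    best: dict[tuple[str, str], SimilarityHit] = {}
    for hit in hits:
        q_sp = species_of(hit.query_id, species_map)
        s_sp = species_of(hit.subject_id, species_map)
        if scope == "cross_species" and q_sp == s_sp:
            continue
        if scope == "within_species" and q_sp != s_sp:
            continue
        key = (hit.query_id, s_sp)
        best[key] = hit if key not in best else _better(best[key], hit)
    return best


def bbh_orthologs(
    best: Mapping[tuple[str, str], SimilarityHit],
    species_map: Optional[Mapping[str, str]] = None,
) -> list[tuple[str, str, float]]:
    """Reciprocal-best-hit ortholog edges ``(a, b, min_evalue)`` with a < b."""
    edges = []
    for (qid, s_sp), hit in best.items():
        sid = hit.subject_id
        q_sp = species_of(qid, species_map)
        back = best.get((sid, q_sp))
        if back is not None and back.subject_id == qid and qid < sid:
            edges.append((qid, sid, min(hit.evalue, back.evalue)))
    edges.sort()
    return edges


def paralog_edges(
    hits: Iterable[SimilarityHit],
    species: str,
    cutoff: float,
    species_map: Optional[Mapping[str, str]] = None,
) -> list[tuple[str, str, float]]:
    """Within-species paralog edges at an E-value cutoff.

    An undirected edge (a, b) is emitted iff both directed hits were
    reported and the better of the two E-values is <= cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    directed: dict[tuple[str, str], float] = {}
    for hit in hits:
        if species_of(hit.query_id, species_map) != species:
            continue
        if species_of(hit.subject_id, species_map) != species:
            continue
        key = (hit.query_id, hit.subject_id)
        directed[key] = min(directed.get(key, float("inf")), hit.evalue)
    edges = []
    for (a, b), e_ab in directed.items():
        if a >= b:
            continue
        e_ba = directed.get((b, a))
        if e_ba is None:
            continue
        e = min(e_ab, e_ba)
        if e <= cutoff:
            edges.append((a, b, e))
    edges.sort()
    return edges


@dataclass
class CutoffSelection:
    species: str
    grid: list[float]
    counts: dict[float, int]
    selected: float
    no_hits: bool = False


def count_paralog_networks(
    edges: Sequence[tuple[str, str, float]],
) -> int:
    """Number of connected components with >= 2 members (edgeless proteins don't count)."""
    g = nx.Graph()
    g.add_edges_from((a, b) for a, b, _ in edges)
    return sum(1 for c in nx.connected_components(g) if len(c) >= 2)


def select_cutoff(
    hits: Iterable[SimilarityHit],
    species: str,
    grid: Sequence[float],
    species_map: Optional[Mapping[str, str]] = None,
) -> CutoffSelection:
    """Scan an E-value grid and pick the cutoff maximising paralog-network count.

    Ties are broken towards the loosest (largest) threshold, which retains
    the most sequences. A species with no within-species hits yields an
    all-zero count map, the loosest grid value, and ``no_hits=True``.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    hits = list(hits)
    counts = {
        float(c): count_paralog_networks(
            paralog_edges(hits, species, float(c), species_map)
        )
        for c in grid
    }
    no_hits = all(v == 0 for v in counts.values())
    best = max(counts.values())
    selected = max(c for c, v in counts.items() if v == best)
    if no_hits:
        logger.warning("species %s: no within-species paralog networks at any cutoff", species)
    return CutoffSelection(species, [float(c) for c in grid], counts, selected, no_hits)


def default_grid(loose: float = 1e-3, strict: float = 1e-18, step_decades: int = 3):
    """E-value grid from loose to strict in ``step_decades`` decade steps.

    The default span covers the "twilight zone" between the reporting
    threshold and the strength of unambiguous family similarity: that is
    where spurious between-family hits live and where the
    network-maximising scan does its work. Scanning far below the
    weakest true within-family E-value is counterproductive — it can
    only fragment genuine families, which inflates the paralog-network
    count for the wrong reason.
    """
    import numpy as np

    lo = np.log10(loose)
    hi = np.log10(strict)
    exps = np.arange(lo, hi - 1e-9, -abs(step_decades))
    return [10.0 ** e for e in exps] + [strict]


@dataclass
class HomologyNetwork:
    network_id: str
    members: set[str]
    edges: list[tuple[str, str, str, float]]  # (a, b, kind, evalue)
    function_labels: dict[str, str] = field(default_factory=dict)

    @property
    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.function_labels.values():
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    @property
    def is_writer_related(self) -> bool:
        return any(l in WRITER_LABELS for l in self.function_labels.values())

    @property
    def is_eraser_related(self) -> bool:
        return any(l in ERASER_LABELS for l in self.function_labels.values())


def build_networks(
    ortholog_edges: Sequence[tuple[str, str, float]],
    paralog_edges_all: Sequence[tuple[str, str, float]],
) -> list[HomologyNetwork]:
    """Connected components of the ortholog + paralog union graph.

    Singleton proteins (no retained edge) form no network. Components are
    ordered by (size descending, smallest member ID) and numbered
    ``NET_1`` ... from 1.
    """
    g = nx.Graph()
    for a, b, e in ortholog_edges:
        g.add_edge(a, b, kind="ortholog", evalue=e)
    for a, b, e in paralog_edges_all:
        if g.has_edge(a, b):
            # an ortholog call cannot coexist with a paralog call for the
            # same pair (different species vs same species); keep existing
            continue
        g.add_edge(a, b, kind="paralog", evalue=e)
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    networks = []
    for k, comp in enumerate(comps, start=1):
        sub = g.subgraph(comp)
        edges = sorted(
            (min(a, b), max(a, b), d["kind"], d["evalue"])
            for a, b, d in sub.edges(data=True)
        )
        networks.append(HomologyNetwork(f"NET_{k}", set(comp), edges))
    return networks


def annotate_networks(
    networks: Sequence[HomologyNetwork],
    annotation: Mapping[str, str],
) -> list[HomologyNetwork]:
    """Attach function labels to every member; unknown members get ``"unknown"``."""
    for net in networks:
        net.function_labels = {
            m: annotation.get(m, "unknown") for m in net.members
        }
    return list(networks)


def inventory_table(
    networks: Sequence[HomologyNetwork],
    species_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Writer/eraser gene-family inventory, one row per (type, gene, species, network).

    Only networks with at least one writer/eraser label are retained, and
    within them only members carrying a writer/eraser label are listed.
    """
    rows = []
    for net in networks:
        if not (net.is_writer_related or net.is_eraser_related):
            continue
        per: dict[tuple[str, str, str], list[str]] = {}
        for member, label in net.function_labels.items():
            if label in WRITER_LABELS:
                typ = "Writers"
            elif label in ERASER_LABELS:
                typ = "Erasers"
            else:
                continue
            per.setdefault((typ, label, species_of(member, species_map)), []).append(member)
        for (typ, gene, sp), members in per.items():
            rows.append(
                {
                    "type": typ,
                    "gene_name": gene,
                    "species": sp,
                    "n_members": len(members),
                    "member_ids": ";".join(sorted(members)),
                    "network_id": net.network_id,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["type", "gene_name", "species", "n_members", "member_ids", "network_id"],
    )
    return df.sort_values(["type", "gene_name", "species"]).reset_index(drop=True)


def _pair_identity(a: str, b: str) -> float:
    """Identity of the pair over the shorter sequence's aligned span."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    # infix alignment: best placement of the shorter within the longer
    res = edlib.align(short, long_, mode="HW", task="distance")
    dist = res["editDistance"]
    return max(0.0, 1.0 - dist / len(short))


def collapse_redundant(
    sequences: Mapping[str, str],
    identity_threshold: float = 0.98,
    overlap_threshold: float = 0.5,
) -> tuple[dict[str, str], dict[str, str]]:
    """Greedy identity-based redundancy collapse (stand-in for assembly tools).

    Sequences are sorted by (length descending, ID); each joins the first
    representative with pairwise identity >= ``identity_threshold`` over
    the shorter sequence's aligned span and length overlap (short/long)
    >= ``overlap_threshold``, otherwise it becomes a new representative.
    Returns (representatives, collapse map member -> representative).
    """
    for thr in (identity_threshold, overlap_threshold):
        if not 0.0 < thr <= 1.0:
            raise ValueError("thresholds must lie in (0, 1]")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    reps: dict[str, str] = {}
    collapse: dict[str, str] = {}
    for sid in order:
        seq = sequences[sid]
        home = None
        for rid, rseq in reps.items():
            overlap = min(len(seq), len(rseq)) / max(len(seq), len(rseq))
            if overlap < overlap_threshold:
                continue
            if _pair_identity(seq, rseq) >= identity_threshold:
                home = rid
                break
        if home is None:
            reps[sid] = seq
        else:
            collapse[sid] = home
    return reps, collapse
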