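"""End-to-end pipeline: collection -> index -> quotient -> graph."""

from __future__ import annotations

from dataclasses import dataclass

from .graph import (
    BidirectedVariationGraph,
    build_singular_graph,
    compress_unbranched,
)
from .kmer_index import KmerIndex, build_kmer_index
from .quotient import AssignmentVector, quotient
from .sequence_io import ConcatenatedText, SequenceCollection, concatenate


@dataclass(frozen=True)
class PipelineResult:
    text: ConcatenatedText
    index: KmerIndex
    assignment: AssignmentVector
    singular: BidirectedVariationGraph
    graph: BidirectedVariationGraph  # compressed unless compress=False


def build_pangenome_graph(
    collection: SequenceCollection, k: int, compress: bool = True
) -> PipelineResult:
    """Build the k-complete, k-faithful bidirected variation graph.

    Runs the full pipeline and returns all intermediate products; ``graph``
    is the compressed graph (or the singular one when ``compress=False``).
    """
    text = concatenate(collection)
    index = build_kmer_index(text, k)
    assignment = quotient(index, text)
    singular = build_singular_graph(text, assignment)
    graph = (
        compress_unbranched(singular, text, assignment)
        if compress
        else singular
    )
    return PipelineResult(
        text=text,
        index=index,
        assignment=assignment,
        singular=singular,
        graph=graph,
    )
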