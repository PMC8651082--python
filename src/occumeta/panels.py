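"""Marker panel registry.

A panel maps a metabolic function ("species" in occupancy terms) to the
marker genes that act as its replicate surveys.  Each marker is one
required subunit of the catalytic enzyme complex, so the K columns of a
detection history are the K subunits screened in a single metagenome.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class MarkerPanel:
    """A function of interest and its ordered replicate-survey markers.

    Parameters
    ----------
    function_name:
        Short name of the function, e.g. ``"MCR"`` (methanogenesis) or
        ``"pMMO"`` (aerobic methanotrophy).
    markers:
        Ordered marker symbols; the order fixes the survey index k.
    ko_ids:
        KEGG Orthology identifier per marker, aligned with ``markers``.
    """

    function_name: str
    markers: tuple[str, ...]
    ko_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.markers) < 1:
            raise ValueError("a panel needs at least one marker")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError(f"duplicate marker symbols in panel {self.function_name!r}")
        if self.ko_ids and len(self.ko_ids) != len(self.markers):
            raise ValueError("ko_ids must align with markers")

    @property
    def n_surveys(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)


# Methyl-coenzyme M reductase: terminal step of methanogenesis.
MCR_PANEL = MarkerPanel(
    function_name="MCR",
    markers=("McrA", "McrB", "McrG"),
    ko_ids=("K00399", "K00401", "K00402"),
)

# Particulate methane monooxygenase: first step of aerobic methane oxidation.
# The Pmo subunits share KO identifiers with the ammonia monooxygenase (Amo)
# homologs, which is why curation against labeled references is required.
PMO_PANEL = MarkerPanel(
    function_name="pMMO",
    markers=("PmoA", "PmoB", "PmoC"),
    ko_ids=("K10944", "K10945", "K10946"),
)

DEFAULT_PANELS: dict[str, MarkerPanel] = {p.function_name: p for p in (MCR_PANEL, PMO_PANEL)}
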