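"""Built-in gene panels.

The 9-gene mitotic gene signature (MGS) and the three 3-gene marker panels
used to classify sympathetic-ganglion cell types (neuroblast, ganglion,
Schwannian) in targeted single-cell qPCR.  Symbols are mouse-style except
``hMYCN``, the human transgene probe.
"""

from .containers import GeneSignature

MGS = GeneSignature(
    "MGS",
    ("Bub1b", "Kif23", "Bub1", "Kifc1", "Aspm", "Plk4", "Depdc1a", "Ccnb2", "Prr11"),
)

NEUROBLAST_MARKERS = GeneSignature("neuroblast", ("Phox2b", "hMYCN", "Dlk1"))
GANGLION_MARKERS = GeneSignature("ganglion", ("Gap43", "Dbh", "Tubb3"))
SCHWANNIAN_MARKERS = GeneSignature("schwannian", ("Sox10", "Col1a2", "S100a1"))

#: full targeted qPCR probe panel: 9 cell-type markers + 9 mitotic genes
SC_PANEL: tuple[str, ...] = (
    NEUROBLAST_MARKERS.genes + GANGLION_MARKERS.genes + SCHWANNIAN_MARKERS.genes + MGS.genes
)

MARKER_SIGNATURES = {
    "neuroblast": NEUROBLAST_MARKERS,
    "ganglion": GANGLION_MARKERS,
    "schwannian": SCHWANNIAN_MARKERS,
}
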