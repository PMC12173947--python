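"""Packaged fixtures.

``dsb_annotations_synthetic.tsv`` is a synthetic stand-in annotation
table for the canonical set of 80 sequence-specific restriction-enzyme
DSB sites: it reproduces the published category totals (65 TC-DSBs, 15
silent, 31 promoter / 36 five-prime / 9 gene-body annotations, 19 exonic
/ 26 intronic, 11 dual-annotated sites) with generic site and gene
identifiers, for use wherever only the category structure matters.
"""

from importlib import resources


def dsb_annotations_path():
    """Path to the synthetic DSB annotation fixture table."""
    return resources.files(__package__) / "dsb_annotations_synthetic.tsv"


def load_dsb_annotations():
    """The fixture as a list of :class:`~dsbstrand.annotate.DSBAnnotation`."""
    from ..annotate import load_annotations

    with resources.as_file(dsb_annotations_path()) as path:
        return load_annotations(path)
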