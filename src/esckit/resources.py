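"""Bundled reference data.

The immune marker-gene signatures follow the marker-mean scheme of Danaher
et al. (2017), with a CD4 T-cell set added after Davoli et al.; the lists
shipped here were reconstructed from the published tables and carry a
provenance note in each set description.  Users can substitute their own
GMT-format signature file anywhere a signature collection is accepted.
"""

from __future__ import annotations

from importlib import resources as _ir

from .io import GeneSetCollection, read_gmt

__all__ = ["danaher_signatures"]


def danaher_signatures() -> GeneSetCollection:
    """The bundled 13-cell-type marker-mean immune signature collection."""
    path = _ir.files("esckit.data") / "immune_signatures_danaher2017.gmt"
    with _ir.as_file(path) as p:
        return read_gmt(p)
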