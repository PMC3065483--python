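"""Packaged Passiflora trait data and the flow-cytometry size formula.

The built-in table holds averaged 1C genome sizes (pg) and flower
diameters (cm) for 50 Passiflora species: 36 from subgenus Passiflora,
13 from subgenus Decaloba, and P. deidamioides (subgenus Deidamioides)
as outgroup.  Genome sizes were estimated by propidium-iodide flow
cytometry against an internal Arabidopsis thaliana Landsberg standard
whose diploid (2C) genome is taken as 0.32 pg.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .phylo_io import TraitTable, read_trait_table

__all__ = ["FlowMeasurement", "load_table1", "gs_from_flow", "ARABIDOPSIS_2C_PG"]

#: 2C genome size of the Arabidopsis Landsberg internal standard, picograms.
ARABIDOPSIS_2C_PG = 0.32


def load_table1() -> TraitTable:
    """Load the packaged 50-species genome-size / flower-diameter table.

    Returns a :class:`~phylocontrast.phylo_io.TraitTable` with columns
    ``species``, ``clade`` (Passiflora / Decaloba / outgroup), ``gs_pg``
    (1C genome size, pg) and ``fd_cm`` (flower diameter, cm), values as
    printed in the source data.
    """
    ref = resources.files("phylocontrast").joinpath("data/table1.csv")
    with resources.as_file(ref) as path:
        return read_trait_table(path)


@dataclass(frozen=True)
class FlowMeasurement:
    """One flow-cytometry run of a sample against an internal standard.

    Attributes
    ----------
    sample_peak_mean:
        Mean fluorescence channel of the sample's G0/G1 peak.
    standard_peak_mean:
        Mean fluorescence channel of the internal standard's G0/G1 peak,
        same units.
    standard_2c_pg:
        Known 2C genome size of the standard, picograms (default: the
        Arabidopsis Landsberg value, 0.32 pg).
    """

    sample_peak_mean: float
    standard_peak_mean: float
    standard_2c_pg: float = ARABIDOPSIS_2C_PG

    def __post_init__(self):
        for name in ("sample_peak_mean", "standard_peak_mean", "standard_2c_pg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def gs_from_flow(m: FlowMeasurement) -> float:
    """1C genome size (pg) from relative peak fluorescence.

    The sample's 2C content is the standard's 2C content scaled by the
    ratio of G0/G1 peak means; halving converts 2C to 1C::

        1C = (sample_peak / standard_peak) * standard_2C / 2

    Linear in the sample peak and invariant to a common rescaling of the
    two peak means (channel calibration cancels).
    """
    return (m.sample_peak_mean / m.standard_peak_mean) * m.standard_2c_pg / 2.0
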