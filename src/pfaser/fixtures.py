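"""Packaged reference data: docking-validation tables and published models.

Fixture names:

* ``table1_era_ligands`` / ``table2_erb_ligands`` — the five synthetic
  (pharmaceutical) reference ligands per receptor, with experimental IC50,
  docking score, docking-derived IC50 and the printed pIC50 difference;
* ``table5_abbreviations`` — letter -> descriptor-name map;
* ``table3_descriptor_sources`` — descriptor -> data-source map;
* ``eq3_tb_era`` .. ``eq6_ce_erb`` (or the model names ``TB-ERalpha`` etc.)
  — the four published equations as :class:`~pfaser.qspr.LinearModel`.
"""

from __future__ import annotations

from importlib import resources

from .descriptors import DESCRIPTOR_LETTERS
from .io import read_table
from .qspr import load_published_model

__all__ = ["load_fixture", "FIXTURE_NAMES"]

_EQ_ALIASES = {
    "eq3_tb_era": "TB-ERalpha",
    "eq4_tb_erb": "TB-ERbeta",
    "eq5_ce_era": "CE-ERalpha",
    "eq6_ce_erb": "CE-ERbeta",
}

#: Descriptor -> acquisition source, for provenance sidecars.
_DESCRIPTOR_SOURCES = {
    "Density": "ChemSpider",
    "Number of H-Bond Acceptors": "ChemSpider",
    "Number of H-Bond Donors": "ChemSpider",
    "Number of Freely Rotating Bonds": "ChemSpider",
    "LogD (pH 7.4)": "ChemSpider",
    "Polar Surface Area": "ChemSpider",
    "Surface Tension": "ChemSpider",
    "HOMO": "Avogadro/MOPAC",
    "LUMO": "Avogadro/MOPAC",
    "Average Mass": "Avogadro/MOPAC",
    "F+ Max": "RowanSci",
}

FIXTURE_NAMES = (
    "table1_era_ligands",
    "table2_erb_ligands",
    "table3_descriptor_sources",
    "table5_abbreviations",
    *(_EQ_ALIASES.keys()),
)


def _read_packaged_csv(name: str):
    text = resources.files("pfaser").joinpath(f"data/{name}.csv").read_text()
    return read_table(text, index_col=None)


def load_fixture(name: str):
    """Return a packaged table (DataFrame), map (dict) or model by name."""
    key = name.lower()
    if key in ("table1_era_ligands", "table2_erb_ligands"):
        return _read_packaged_csv(key)
    if key == "table5_abbreviations":
        return dict(DESCRIPTOR_LETTERS)
    if key == "table3_descriptor_sources":
        return dict(_DESCRIPTOR_SOURCES)
    if key in _EQ_ALIASES:
        return load_published_model(_EQ_ALIASES[key])
    try:
        return load_published_model(name)
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_NAMES)}"
        ) from None
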