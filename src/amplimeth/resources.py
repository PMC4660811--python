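"""Accessors for the packaged demo fixtures.

The package ships a transcription of the study design it was built around:
the 48-target multiplex bisulfite PCR panel (amplicon config), the 86-sample
manifest, and a small simulation spec on real panel coordinates. Rows whose
genomic span or content could not be recovered from the source tables carry
documented placeholders (see the fixture file headers).
"""

from importlib import resources
from pathlib import Path

_DATA = resources.files(__package__) / "data"


def panel_amplicon_config_path() -> Path:
    """BED-like config for the 48-amplicon multiplex panel (0-based)."""
    return Path(str(_DATA / "multiplex_panel_amplicons.tsv"))


def study_sample_manifest_path() -> Path:
    """Tab-separated manifest of the 86 study samples."""
    return Path(str(_DATA / "study_samples.tsv"))


def demo_simspec_path() -> Path:
    """JSON simulation spec: two epiallele mixtures plus the no-CpG control."""
    return Path(str(_DATA / "demo_simspec.json"))
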