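"""Published per-chromosome linkage-map summaries for four rice RIL
populations, transcribed at print precision.

Four biparental F7 RIL populations share Koshihikari as the common parent:

======  =======  =============  ==========================
pop     n lines  founder        retained integrated markers
======  =======  =============  ==========================
RIL71   190      Yamadanishiki  527
RIL98   96       Taichung 65    455
RIL16   95       Fujisaka 5     501
RIL91   94       Futaba         436
======  =======  =============  ==========================

Two map kinds are available per population: ``integrated`` (GoldenGate SNPs
plus random-amplicon markers, co-localized markers removed) and
``goldengate`` (array SNPs only).  The tables carry per-chromosome marker
counts, map lengths, mean marker intervals, and the largest inter-marker
gap with its flanking markers and physical (Mb) coordinates, at the
precision the study printed (cM to 1 decimal, Mb to 2).
"""

from __future__ import annotations

from importlib import resources

from .linkage import MapSummary

POPULATIONS = ("ril71", "ril98", "ril16", "ril91")
MAP_KINDS = ("integrated", "goldengate")

#: final progeny count per population
N_LINES = {"ril71": 190, "ril98": 96, "ril16": 95, "ril91": 94}

#: random-amplicon-platform marker yields (SNPs, dominant amplicons)
GRASDI_MARKERS = {
    "ril71": (495, 555),
    "ril98": (499, 786),
    "ril16": (593, 1115),
    "ril91": (635, 1069),
}

#: integrated map totals including co-localized markers
INTEGRATED_WITH_COLOCALIZED = {"ril71": 1360, "ril98": 1605, "ril16": 2018, "ril91": 2056}

#: Nipponbare IRGSP-1.0 reference genome size used for marker-density arithmetic
GENOME_SIZE_BP = 373e6


def load_published_summary(population: str, kind: str = "integrated") -> MapSummary:
    """Published per-chromosome map summary for one population.

    ``kind`` is ``"integrated"`` (both platforms, co-localized markers
    removed) or ``"goldengate"`` (array SNPs only).
    """
    population = population.lower()
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}; choose from {POPULATIONS}")
    if kind not in MAP_KINDS:
        raise ValueError(f"unknown map kind {kind!r}; choose from {MAP_KINDS}")
    from .io import read_map_summary  # local import avoids a cycle

    ref = resources.files("rilmap").joinpath(f"data/published_maps/{kind}_{population}.tsv")
    with resources.as_file(ref) as path:
        return read_map_summary(path)
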