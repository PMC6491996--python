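"""Packaged example data sets.

Four small studies spanning the data types the planner handles:

* ``epilepsy`` — counts: 28 placebo seizure counts from an epilepsy trial,
  paired with the synthetic alternative floor(0.5 * x) (a 50 % seizure
  reduction).
* ``nasal`` — ordinal: rats' nasal-mucosa defect scores 0-3 under an
  inhalable substance (counts 64/12/4/0), with the alternative moving 25 %
  of scores 0-2 one unit worse (48/25/6/1).
* ``kidney`` — continuous: relative kidney weights of 8 male Wistar rats
  on placebo, with the alternative shifted by 5 % of the placebo mean and
  rounded to the measurement precision of 2 decimals.
* ``albumin`` — near-dichotomous ordinal: expected probabilities of
  normal / micro- / macroalbuminuria under control (0.85/0.10/0.05) and
  experimental (0.90/0.075/0.025) treatment.

Payloads are stored as plain CSV inside the package and returned either as
a pair of observation arrays or as a :class:`~wmwdesign.ranks.FrequencyTable`.
"""

from __future__ import annotations

from importlib import resources

from .io import read_frequency_csv, read_long_csv

__all__ = ["FIXTURES", "load_fixture", "fixture_kind"]

#: fixture name -> ("long" | "frequency", packaged csv file)
FIXTURES = {
    "epilepsy": ("long", "epilepsy.csv"),
    "nasal": ("frequency", "nasal.csv"),
    "kidney": ("long", "kidney.csv"),
    "albumin": ("frequency", "albumin.csv"),
}


def fixture_kind(name: str) -> str:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    return FIXTURES[name][0]


def load_fixture(name: str):
    """Load a packaged data set by name.

    Returns ``(sample1, sample2)`` arrays for long-format fixtures and a
    :class:`FrequencyTable` for ordered-categorical ones.
    """
    kind = fixture_kind(name)
    fname = FIXTURES[name][1]
    path = resources.files("wmwdesign.data").joinpath(fname)
    with resources.as_file(path) as p:
        return read_long_csv(p) if kind == "long" else read_frequency_csv(p)
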