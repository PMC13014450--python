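"""Published reference values for the TmY/EcY CheY comparison.

These are *inputs*, not results: pooled descriptor means, crystal-structure
residue counts and per-pair salt-bridge frequency tables as printed in the
source study.  They feed the worked-example checks and the report layer's
percent-change arithmetic.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .interactions import ResidueRef, SaltBridgeObservation

__all__ = [
    "TEMPERATURES_K",
    "MEAN_RMSD_NM",
    "MEAN_Q",
    "CRYSTAL_SS_COUNTS",
    "RESOLVED_RESIDUES",
    "POLAR_RESIDUES",
    "ILV_COUNTS",
    "load_saltbridge_table",
]

TEMPERATURES_K = (302.0, 328.0, 374.0, 400.0, 450.0)

# pooled mean RMSD (nm) over three replicas, by protein and temperature
MEAN_RMSD_NM = {
    "TmY": {302.0: 0.131, 400.0: 0.184, 450.0: 0.273},
    "EcY": {302.0: 0.250, 400.0: 0.502, 450.0: 1.193},
}

# pooled mean fraction of native contacts
MEAN_Q = {
    "TmY": {302.0: 0.939, 400.0: 0.898, 450.0: 0.792},
    "EcY": {302.0: 0.884, 400.0: 0.657, 450.0: 0.311},
}

# crystal-structure residue counts per category
CRYSTAL_SS_COUNTS = {
    "TmY": {"alpha_helix": 55, "beta_strand": 25, "three_ten": 3, "coil": 35},
    "EcY": {"alpha_helix": 58, "beta_strand": 22, "coil": 48},
}

RESOLVED_RESIDUES = {"TmY": 118, "EcY": 128}

POLAR_RESIDUES = {"TmY": 49, "EcY": 54}

# Ile/Leu/Val membership of the three-state classes (count, class total)
ILV_COUNTS = {
    "TmY": {"beta": (10, 25), "alpha": (12, 55)},
    "EcY": {"beta": (10, 22), "alpha": (14, 58)},
}


def load_saltbridge_table(
    protein: str,
) -> tuple[dict[float, list[SaltBridgeObservation]], dict[tuple, str]]:
    """Load the published per-pair salt-bridge frequencies.

    Returns ``(observations_by_temperature, element_labels)`` where the
    observations carry the printed replica-mean frequency (per-replica
    presence is not published) and ``element_labels`` maps residue-pair
    keys to the printed secondary-structure annotation.
    """
    fname = f"data/saltbridge_frequencies_{protein.lower()}.tsv"
    text = resources.files("thermotraj").joinpath(fname).read_text()
    by_temp: dict[float, list[SaltBridgeObservation]] = {t: [] for t in TEMPERATURES_K}
    labels: dict[tuple, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        basic_s, acidic_s, elements, *freqs = line.split("\t")
        basic = ResidueRef("A", int(basic_s[3:]), basic_s[:3])
        acidic = ResidueRef("A", int(acidic_s[3:]), acidic_s[:3])
        labels[(basic, acidic)] = elements
        for temp, f in zip(TEMPERATURES_K, map(float, freqs)):
            by_temp[temp].append(
                SaltBridgeObservation(
                    basic_residue=basic,
                    acidic_residue=acidic,
                    r_max=4.0,
                    presence=[],
                    f_per_replica=np.array([f]),
                    f_mean=f,
                )
            )
    return by_temp, labels
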