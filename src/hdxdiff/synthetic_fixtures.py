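"""Synthetic DynamX-dialect cluster files with known ground truth.

The generator emulates what the upstream Waters pipeline exports: for a
fictitious protein it draws peptide spans, per-amide exchange rates and
per-peptide back-exchange factors, then renders replicate-level centroid
m/z rows across states, exposures and charge states with Gaussian mass
noise and log-normal intensities.  True uptake kinetics follow the
standard exponential exchange model

    D(t) = deuterium_fraction * sum_k (1 - exp(-k_k * t))

with optional per-peptide, per-state uptake offsets injected as known
effects.  Everything is driven by a :class:`SimulationManifest`, and the
same manifest always yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hdxdiff.cluster_io import (Dataset, exchangeable_amides,
                                write_cluster_csv)
from hdxdiff.uptake_core import PROTON_MASS

# monoisotopic residue masses (Da); MHP = sum + water + proton
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.010565

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class SimulationError(ValueError):
    pass


@dataclass
class SimulationManifest:
    """Full description of one simulated differential HDX-MS experiment.

    Effects are deuterium-uptake offsets in Da injected into a state's
    peptides at every non-zero exposure: ``effects[state][peptide_index]``.
    The first state in ``states`` is the reference and normally carries no
    effect.  Back-exchange is a per-peptide multiplicative recovery factor
    drawn from ``back_exchange_range`` (1.0 means no loss).
    """
    seed: int = 0
    protein: str = "SIMPROT"
    protein_length: int = 120
    n_peptides: int = 40
    states: tuple = ("APO", "HOLO")
    effects: dict = field(default_factory=dict)   # state -> {pep_idx: Da}
    exposures: tuple = (0.0, 0.5, 5.0, 30.0)
    replicates: int = 3
    max_charge: int = 3
    noise_sd: float = 0.05          # Da, labelling noise per deuterated row
    centroid_noise_sd: float = 0.01  # Da, centroid determination, all rows
    intensity_mu: float = 11.0      # log-scale of log-normal intensities
    intensity_sigma: float = 0.6
    back_exchange_range: tuple = (0.65, 0.85)
    deuterium_fraction: float = 0.9
    control_state: str | None = None   # e.g. "MAX": maximally labelled control

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["effects"] = {s: {str(k): v for k, v in eff.items()}
                        for s, eff in self.effects.items()}
        return json.dumps(d, indent=2, default=lambda o: list(o)
                          if isinstance(o, tuple) else o)


def simulate_uptake_curve(n_amides: int, rates, exposure: float,
                          deuterium_fraction: float = 0.9) -> float:
    """Exponential exchange kinetics: ``D(t) = f * sum_k (1 - exp(-k t))``."""
    rates = np.asarray(rates, dtype=float)
    if len(rates) != n_amides or np.any(rates < 0):
        raise SimulationError("need one non-negative rate per amide")
    if exposure < 0:
        raise SimulationError("negative exposure")
    return float(deuterium_fraction * np.sum(1.0 - np.exp(-rates * exposure)))


def _draw_peptides(manifest: SimulationManifest, rng: np.random.Generator):
    """Distinct peptide spans with sequences, masses and exchange rates."""
    peptides = []
    seen = set()
    attempts = 0
    while len(peptides) < manifest.n_peptides:
        attempts += 1
        if attempts > 100 * manifest.n_peptides:
            raise SimulationError("cannot place the requested peptides; "
                                  "protein too short")
        max_len = min(15, manifest.protein_length)
        if max_len < 6:
            raise SimulationError("protein too short for peptides")
        length = int(rng.integers(6, max_len + 1))
        start = int(rng.integers(1, manifest.protein_length - length + 2))
        end = start + length - 1
        if (start, end) in seen:
            continue
        seen.add((start, end))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        n_amides = exchangeable_amides(seq)
        if n_amides < 3:
            seen.discard((start, end))
            continue
        mhp = sum(RESIDUE_MASS[a] for a in seq) + WATER + PROTON_MASS
        rates = 10.0 ** rng.uniform(-2.5, 1.0, size=n_amides)  # 1/min
        n_charges = min(int(rng.integers(1, 3)), manifest.max_charge)
        charges = sorted(rng.choice(np.arange(1, manifest.max_charge + 1),
                                    size=n_charges, replace=False))
        peptides.append({"start": start, "end": end, "sequence": seq,
                         "max_uptake": n_amides, "mhp": mhp, "rates": rates,
                         "charges": [int(z) for z in charges],
                         "rt": float(rng.uniform(2.0, 14.0))})
    peptides.sort(key=lambda p: (p["start"], p["end"]))
    return peptides


def generate_cluster_file(manifest: SimulationManifest, path=None,
                          truth_path=None, manifest_path=None
                          ) -> tuple[Dataset, pd.DataFrame]:
    """Render the manifest into cluster records and a truth table.

    Returns ``(dataset, truth)``; when paths are given, also writes the
    cluster CSV, the truth CSV and a JSON echo of the manifest.  The truth
    table holds, per peptide x state x non-zero exposure, the pre- and
    post-back-exchange true uptake, the injected effect, and the true
    uptake difference versus the reference state — the labels every
    downstream recovery test scores against.
    """
    rng = np.random.default_rng(manifest.seed)
    peptides = _draw_peptides(manifest, rng)
    n = len(peptides)
    bx = rng.uniform(*manifest.back_exchange_range, size=n)

    all_states = list(manifest.states)
    if manifest.control_state:
        all_states.append(manifest.control_state)
    ref_state = manifest.states[0]

    rows, truth_rows = [], []
    for idx, pep in enumerate(peptides):
        plateau = manifest.deuterium_fraction * pep["max_uptake"]
        # true uptake per state and exposure; effects are clipped to the
        # physical range, so the truth table stores the REALIZED difference
        d_true: dict[tuple, float] = {}
        for state in all_states:
            effect = float(manifest.effects.get(state, {}).get(idx, 0.0))
            for exposure in manifest.exposures:
                if exposure == 0:
                    d = 0.0
                elif state == manifest.control_state:
                    d = plateau
                else:
                    base = simulate_uptake_curve(
                        pep["max_uptake"], pep["rates"], exposure,
                        manifest.deuterium_fraction)
                    d = float(np.clip(base + effect, 0.0, plateau))
                d_true[(state, exposure)] = d

        for state in all_states:
            for exposure in manifest.exposures:
                d_obs = bx[idx] * d_true[(state, exposure)]
                # labelling noise only affects deuterated samples; the
                # non-deuterated reference carries centroid noise alone
                row_sd = np.hypot(manifest.centroid_noise_sd,
                                  manifest.noise_sd if exposure > 0 else 0.0)
                for rep in range(1, manifest.replicates + 1):
                    for z in pep["charges"]:
                        neutral = (pep["mhp"] - PROTON_MASS + d_obs
                                   + rng.normal(0.0, row_sd))
                        rows.append({
                            "protein": manifest.protein,
                            "start": pep["start"], "end": pep["end"],
                            "sequence": pep["sequence"], "modification": "",
                            "fragment": "",
                            "max_uptake": float(pep["max_uptake"]),
                            "mhp": pep["mhp"], "state": state,
                            "exposure": exposure,
                            "raw_file": f"{state}_rep{rep}.raw",
                            "charge": z,
                            "retention_time": pep["rt"],
                            "intensity": float(rng.lognormal(
                                manifest.intensity_mu - 0.4 * (z - pep["charges"][0]),
                                manifest.intensity_sigma)),
                            "center": (neutral + z * PROTON_MASS) / z,
                        })
                if exposure > 0 and state in manifest.states:
                    effect = float(manifest.effects.get(state, {}).get(idx, 0.0))
                    delta = d_true[(state, exposure)] - d_true[(ref_state, exposure)]
                    truth_rows.append({
                        "peptide_index": idx,
                        "start": pep["start"], "end": pep["end"],
                        "sequence": pep["sequence"], "modification": "",
                        "state": state, "exposure": exposure,
                        "max_uptake": pep["max_uptake"],
                        "back_exchange_factor": bx[idx],
                        "effect": effect,
                        "d_true": d_true[(state, exposure)],
                        "d_observed": d_obs,
                        "true_delta_vs_ref": delta,
                        "true_delta_observed": bx[idx] * delta,
                        "truly_affected": delta != 0,
                    })

    dataset = Dataset(pd.DataFrame(rows))
    truth = pd.DataFrame(truth_rows)
    if path is not None:
        write_cluster_csv(dataset, path)
    if truth_path is not None:
        truth.to_csv(truth_path, index=False, float_format="%.9g")
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            fh.write(manifest.to_json() + "\n")
    return dataset, truth


def simulate_replicate_table(n_peptides: int = 100, seed: int = 0,
                             effect: float = 0.0, noise_sd: float = 0.05,
                             exposures=(0.5, 5.0, 30.0), replicates: int = 3,
                             states=("APO", "HOLO")) -> pd.DataFrame:
    """Replicate-level uptake table simulated directly (no file round trip).

    Uptake of every replicate is ``D(t) + N(0, noise_sd)`` with a random
    exchange curve per peptide and the constant ``effect`` (Da) added to
    the second state.  Intensities are uniform, so the statistical
    behaviour is exactly iid Gaussian — the clean setting for calibrating
    the significance tests.  Columns match the output of
    :func:`hdxdiff.uptake_core.compute_replicate_uptake`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_peptides):
        start = 3 * i + 1
        length = 8
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        n_am = max(exchangeable_amides(seq), 3)
        rates = 10.0 ** rng.uniform(-2.5, 1.0, size=n_am)
        for state_idx, state in enumerate(states):
            for t in exposures:
                base = simulate_uptake_curve(n_am, rates, t, 0.9)
                if state_idx == 1:
                    base += effect
                for rep in range(1, replicates + 1):
                    rows.append({
                        "protein": "SIMPROT", "start": start,
                        "end": start + length - 1, "sequence": seq,
                        "modification": "", "max_uptake": float(n_am),
                        "state": state, "exposure": float(t),
                        "raw_file": f"{state}_rep{rep}.raw", "charge": 2,
                        "intensity": 1.0,
                        "uptake": base + rng.normal(0.0, noise_sd),
                    })
    return pd.DataFrame(rows)


def null_manifest(seed: int = 0, **overrides) -> SimulationManifest:
    """Two identically-distributed states, no injected effects."""
    return SimulationManifest(seed=seed, **overrides)


def effect_manifest(seed: int = 0, effect_size: float = 1.0,
                    n_affected: int = 10, sign: str = "positive",
                    **overrides) -> SimulationManifest:
    """Two states where the first ``n_affected`` peptides of the altered
    state carry a known uptake offset (Da); ``sign`` may be "positive",
    "negative" or "alternating"."""
    m = SimulationManifest(seed=seed, **overrides)
    if n_affected > m.n_peptides:
        raise SimulationError("n_affected exceeds n_peptides")
    signs = {"positive": lambda i: 1.0,
             "negative": lambda i: -1.0,
             "alternating": lambda i: 1.0 if i % 2 == 0 else -1.0}[sign]
    altered = m.states[1]
    m.effects = {altered: {i: signs(i) * effect_size for i in range(n_affected)}}
    return m
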