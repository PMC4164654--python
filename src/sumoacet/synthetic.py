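"""Synthetic proteins, site annotations and provider tables.

The generator emulates the statistical structure of a sumoylation-versus-
acetylation window dataset so that the whole pipeline can run and be
validated without external databases or predictors:

* class imbalance — 218 positive (sumoylation) vs. 2780 negative
  (acetylation) windows by default, one protein per window;
* a ΨKXE-like motif in positives: with probability ``motif_prob`` a positive
  window carries an aliphatic residue (V, I or L, with V/I favored) at window
  site 10 and a glutamate at site 13;
* lysine enrichment in the flanks of negative windows, mirroring the
  K-rich context of acetylated lysines;
* class-dependent secondary structure (excess of the non-regular "other"
  state at configurable sites of positives), optional solvent-accessibility
  shifts, and class-shifted per-residue disorder scores at a set of
  downstream sites;
* provider tables (PSSM, 3-state secondary structure, 2-state solvent
  accessibility, disorder scores) written in the exact dialects the encoders
  read, so the generator doubles as a format fixture.

The PSSM of a residue is a noisy own-residue profile (a positive score in
the residue's own column, negative elsewhere), so sequence-level class
differences — the motif and the K enrichment — propagate into the PSSM block
the way conservation differences would.

``planted_descriptors`` returns the ground-truth signal ledger: the primary
carrier column of every planted effect channel.  Secondary encodings of the
same underlying effect (the five Atchley projections of a motif residue, or
the complementary bits of a shifted one-hot pair) are deliberately not
listed: a redundancy-minimizing selector is expected to retain one
representative per channel, and the PSSM (respectively the shifted one-hot
state itself) is the strongest such representative.  The diffuse K
enrichment of negative flanks is a background realism term spread thinly
over many columns and is likewise not ledgered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .feature_encoding import (
    AA_FACTOR,
    DISORDER,
    PSSM,
    SECONDARY_STRUCTURE,
    SOLVENT_ACCESSIBILITY,
    FeatureDescriptor,
    ProviderBundle,
    descriptor_table,
    write_providers,
)
from .peptide_windows import (
    ACETYLATION,
    CENTER_SLOT,
    FLANK,
    STANDARD_AA,
    SUMOYLATION,
    WINDOW_SIZE,
    ProteinRecord,
)

# Average amino-acid composition of well-annotated proteomes (normalized at
# load); used as the background residue distribution.
_BACKGROUND = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0674, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0582, "L": 0.0966,
    "M": 0.0241, "N": 0.0406, "P": 0.0472, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}


def default_background() -> np.ndarray:
    v = np.array([_BACKGROUND[aa] for aa in STANDARD_AA])
    return v / v.sum()


#: Aliphatic motif residues at site 10 and their draw weights (V/I dominate).
PSI_RESIDUES = ("V", "I", "L")
PSI_WEIGHTS = (0.4, 0.4, 0.2)

# Base per-residue state distributions shared by both classes.
_SS_BASE = {"H": 0.30, "E": 0.20, "O": 0.50}
_SA_BASE = {"B": 0.45, "X": 0.55}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    ``motif_prob`` is the probability that a positive window carries the
    planted Ψ/E motif at sites 10 and 13; ``neg_K_enrichment`` is the excess
    probability of lysine at each flanking window site of negatives.
    ``ss_other_shift`` maps window sites to the excess probability of the
    'other' secondary-structure state in positives (taken proportionally from
    helix and strand); ``sa_exposed_shift`` does the same for the 'exposed'
    state.  Disorder scores are Beta-distributed with mean
    ``disorder_mean_pos`` / ``disorder_mean_neg`` at ``disorder_shift_sites``
    of the respective class and 0.5 elsewhere.
    """

    n_pos: int = 218
    n_neg: int = 2780
    seed: int = 0
    motif_prob: float = 0.8
    neg_K_enrichment: float = 0.10
    background: np.ndarray = field(default_factory=default_background)
    ss_other_shift: dict[int, float] = field(default_factory=lambda: {13: 0.2})
    sa_exposed_shift: dict[int, float] = field(default_factory=dict)
    disorder_mean_pos: float = 0.65
    disorder_mean_neg: float = 0.55
    disorder_shift_sites: tuple[int, ...] = (12, 14, 15, 16)
    disorder_concentration: float = 20.0
    pssm_match_score: float = 4.0
    pssm_mismatch_score: float = -1.0
    pssm_noise_sd: float = 1.0
    terminal_prob: float = 0.1
    max_extra_flank: int = 5

    def validate(self) -> None:
        for name in ("motif_prob", "neg_K_enrichment", "terminal_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability")
        for table in (self.ss_other_shift, self.sa_exposed_shift):
            for site, shift in table.items():
                if not 1 <= site <= WINDOW_SIZE:
                    raise ValueError(f"shift site {site} outside 1..{WINDOW_SIZE}")
                if not 0.0 <= shift <= 1.0:
                    raise ValueError(f"shift {shift} at site {site} is not a probability")
        for name in ("disorder_mean_pos", "disorder_mean_neg"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie strictly in (0, 1)")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a 20-vector summing to 1")
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("need at least 2 windows per class")


def _motif_site_residue_distributions(
    config: GeneratorConfig,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Analytic per-class residue distributions at the motif sites 10 and 13."""
    bg = np.asarray(config.background, dtype=float)
    idx = {aa: i for i, aa in enumerate(STANDARD_AA)}
    mp, ke = config.motif_prob, config.neg_K_enrichment

    neg = (1.0 - ke) * bg
    neg[idx["K"]] += ke

    psi = np.zeros(20)
    for aa, w in zip(PSI_RESIDUES, PSI_WEIGHTS):
        psi[idx[aa]] = w
    e_point = np.zeros(20)
    e_point[idx["E"]] = 1.0

    return {
        10: (mp * psi + (1.0 - mp) * bg, neg),
        13: (mp * e_point + (1.0 - mp) * bg, neg),
    }


def _best_factor(pos: np.ndarray, neg: np.ndarray) -> str:
    """The Atchley factor with the largest standardized class difference.

    Given the two class-conditional residue distributions of a site, each
    factor's class means and variances follow analytically; the carrier is
    the factor maximizing |mean difference| / pooled standard deviation.
    """
    from .feature_encoding import ATCHLEY_FACTORS, FACTOR_NAMES

    table = np.array([ATCHLEY_FACTORS[aa] for aa in STANDARD_AA])  # (20, 5)
    best, best_z = None, -1.0
    for j, name in enumerate(FACTOR_NAMES):
        f = table[:, j]
        mu_p, mu_n = pos @ f, neg @ f
        var_p = pos @ f**2 - mu_p**2
        var_n = neg @ f**2 - mu_n**2
        z = abs(mu_p - mu_n) / np.sqrt(0.5 * (var_p + var_n))
        if z > best_z:
            best, best_z = name, z
    return best


def planted_descriptors(config: GeneratorConfig) -> list[FeatureDescriptor]:
    """Ground-truth informative columns: one primary carrier per effect channel.

    For the sequence motif, the carriers are the PSSM columns of the planted
    residues (the profile score is a near-direct residue indicator) plus, at
    each motif site, the single Atchley factor whose analytic standardized
    class difference is largest — the factor-channel representative a
    redundancy-minimizing selector is expected to keep.
    """
    lookup = {d.key: d for d in descriptor_table()}
    keys: list[tuple[str, int, str]] = []
    if config.motif_prob > 0:
        keys += [(PSSM, 10, aa) for aa in PSI_RESIDUES]
        keys.append((PSSM, 13, "E"))
        for site, (pos, neg) in sorted(_motif_site_residue_distributions(config).items()):
            keys.append((AA_FACTOR, site, _best_factor(pos, neg)))
    for site, shift in sorted(config.ss_other_shift.items()):
        if shift != 0:
            keys.append((SECONDARY_STRUCTURE, site, "other"))
    for site, shift in sorted(config.sa_exposed_shift.items()):
        if shift != 0:
            keys.append((SOLVENT_ACCESSIBILITY, site, "exposed"))
    if config.disorder_mean_pos != config.disorder_mean_neg:
        keys += [(DISORDER, s, "score") for s in sorted(config.disorder_shift_sites)]
    return [lookup[k] for k in keys]


def _draw_sequence(
    rng: np.random.Generator,
    config: GeneratorConfig,
    positive: bool,
) -> tuple[str, int]:
    """One protein hosting one modified lysine; returns (sequence, site position)."""
    truncate_up = truncate_down = False
    if rng.random() < config.terminal_prob:
        # place the site near a terminus so the window needs BLANK padding
        if rng.random() < 0.5:
            truncate_up = True
        else:
            truncate_down = True
    if truncate_up:
        up = int(rng.integers(0, FLANK))
    else:
        up = FLANK + int(rng.integers(0, config.max_extra_flank + 1))
    if truncate_down:
        down = int(rng.integers(0, FLANK))
    else:
        down = FLANK + int(rng.integers(0, config.max_extra_flank + 1))
    length = up + 1 + down
    letters = list(rng.choice(list(STANDARD_AA), size=length, p=config.background))
    center = up + 1  # 1-based
    letters[center - 1] = "K"
    if positive:
        if rng.random() < config.motif_prob:
            psi = rng.choice(PSI_RESIDUES, p=PSI_WEIGHTS)
            for slot, aa in ((10, psi), (13, "E")):
                pos = center + (slot - CENTER_SLOT)
                if 1 <= pos <= length:
                    letters[pos - 1] = aa
    else:
        for slot in range(1, WINDOW_SIZE + 1):
            if slot == CENTER_SLOT:
                continue
            pos = center + (slot - CENTER_SLOT)
            if 1 <= pos <= length and rng.random() < config.neg_K_enrichment:
                letters[pos - 1] = "K"
    return "".join(letters), center


def _window_slot(position: int, center: int) -> int | None:
    """The window slot covering a 1-based protein position, if any."""
    slot = position - center + CENTER_SLOT
    return slot if 1 <= slot <= WINDOW_SIZE else None


def _draw_providers(
    rng: np.random.Generator,
    config: GeneratorConfig,
    sequence: str,
    center: int,
    positive: bool,
) -> ProviderBundle:
    n = len(sequence)
    aa_index = {aa: i for i, aa in enumerate(STANDARD_AA)}

    pssm = np.full((n, 20), config.pssm_mismatch_score)
    for i, aa in enumerate(sequence):
        pssm[i, aa_index[aa]] = config.pssm_match_score
    pssm += rng.normal(0.0, config.pssm_noise_sd, size=(n, 20))

    ss_chars = []
    sa_chars = []
    disorder = np.empty(n)
    conc = config.disorder_concentration
    for i in range(n):
        slot = _window_slot(i + 1, center)

        probs = dict(_SS_BASE)
        shift = config.ss_other_shift.get(slot, 0.0) if (positive and slot) else 0.0
        if shift:
            scale = (1.0 - (probs["O"] + shift)) / (1.0 - probs["O"])
            probs = {"H": probs["H"] * scale, "E": probs["E"] * scale,
                     "O": probs["O"] + shift}
        ss_chars.append(rng.choice(list("HEO"), p=[probs["H"], probs["E"], probs["O"]]))

        p_exposed = _SA_BASE["X"]
        if positive and slot:
            p_exposed = min(1.0, p_exposed + config.sa_exposed_shift.get(slot, 0.0))
        sa_chars.append("X" if rng.random() < p_exposed else "B")

        mean = 0.5
        if slot in config.disorder_shift_sites:
            mean = config.disorder_mean_pos if positive else config.disorder_mean_neg
        disorder[i] = rng.beta(mean * conc, (1.0 - mean) * conc)

    return ProviderBundle(
        pssm=pssm, ss="".join(ss_chars), sa="".join(sa_chars), disorder=disorder
    )


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[ProteinRecord], pd.DataFrame, dict[str, ProviderBundle]]:
    """Draw the full synthetic dataset.

    Returns protein records (one annotated lysine each), the site-annotation
    table (protein_id, position, mod_type) and the per-protein provider
    bundles.  The same config and seed reproduce byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    providers: dict[str, ProviderBundle] = {}
    site_rows = []
    specs = [(True, i) for i in range(config.n_pos)] + [
        (False, i) for i in range(config.n_neg)
    ]
    for positive, i in specs:
        pid = f"SYN{'P' if positive else 'N'}{i + 1:05d}"
        seq, center = _draw_sequence(rng, config, positive)
        mod = SUMOYLATION if positive else ACETYLATION
        records.append(ProteinRecord(pid, seq, [(center, mod)]))
        providers[pid] = _draw_providers(rng, config, seq, center, positive)
        site_rows.append({"protein_id": pid, "position": center, "mod_type": mod})
    site_table = pd.DataFrame(site_rows, columns=["protein_id", "position", "mod_type"])
    return records, site_table, providers


def write_dataset(
    records: list[ProteinRecord],
    site_table: pd.DataFrame,
    providers: Mapping[str, ProviderBundle],
    outdir: Union[str, Path],
) -> None:
    """Write FASTA, site table and the four provider TSVs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "proteins.fasta", "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
    site_table.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    write_providers(
        providers,
        outdir / "pssm.tsv",
        outdir / "ss.tsv",
        outdir / "sa.tsv",
        outdir / "disorder.tsv",
    )
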