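"""Simulation of nascent-transcriptome count data after nuclear transfer.

The generator emulates the structure of a BrUTP-labelling NT experiment:
donor cells of several types (ESC, MEF, MYO) have type-specific expression
profiles, while after transfer the oocyte drives inducible genes toward a
shared induced state regardless of donor type. NT counts model *nascent*
transcription only — no carried-over donor RNA — so an induced gene's NT
level is its shared induced target, not a mixture with the donor level.

Per-gene response classes are drawn first and expression levels are then
constructed to satisfy them:

* ``activated``  — silent in the donor (below the expressed cut),
  induced to the shared target after NT;
* ``enhanced``   — expressed in the donor, induced further (fold change
  well above the enhancement cut);
* ``repressed``  — expressed in the donor, transcribed at a lower rate
  after NT;
* ``unchanged``  — nascent transcription mirrors the donor level, which
  is a shared per-gene base times a moderate cell-type effect.

A configurable fraction of inducible genes per cell type is forced
*resistant*: in that focal cell type the NT level stays at the donor level
(no induction) while the other cell types still reach the shared target.
Resistant sets are drawn disjointly across cell types, mirroring the
cell-type-specific resistance asymmetry (adult MYO ≫ embryonic ESC/MEF).

TPM is compositional (each sample sums to 10^6), so the recorded truth
carries two views: generative *levels* (the construction, on which a
resistant gene's NT level exactly equals its donor level) and expected
*TPM* (each condition column renormalized to 10^6 — exactly what TPM
quantification converges to in the noise-free limit). Truth classes are
assigned by applying the construction thresholds (expressed/inducible
TPM 1, fold change 2, pseudocount 1) to the expected TPM, so a noise-free
analysis recovers them perfectly.

48 h NT samples re-sample the same per-gene means as 24 h (a fresh
negative-binomial draw), reflecting that reprogramming is essentially
complete by 24 h.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gvreprog.containers import CountMatrix

CLASSES = ("activated", "enhanced", "repressed", "unchanged")


def _default_proportions() -> dict[str, float]:
    return {"activated": 0.16, "enhanced": 0.10, "repressed": 0.14, "unchanged": 0.60}


def _default_resistant() -> dict[str, float]:
    return {"ESC": 0.04, "MEF": 0.03, "MYO": 0.10}


@dataclass
class ExprSimConfig:
    """Parameters of the expression simulation.

    ``class_proportions`` must sum to 1; ``resistant_fraction`` maps each
    cell type to the fraction of its inducible (activated or enhanced)
    genes forced resistant. ``donor_mean_log2`` is the (mean, sd) of log2
    base expression for expressed unchanged genes and
    ``celltype_sd_log2`` the sd of the per-cell-type donor effect around
    that base. ``nb_dispersion`` is the negative-binomial dispersion
    (variance = μ + φμ²; 0 gives the Poisson limit).
    """

    n_genes: int = 5000
    cell_types: tuple[str, ...] = ("ESC", "MEF", "MYO")
    class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    resistant_fraction: dict[str, float] = field(default_factory=_default_resistant)
    donor_mean_log2: tuple[float, float] = (4.0, 2.0)
    celltype_sd_log2: float = 0.5
    silent_fraction_unchanged: float = 0.3
    nb_dispersion: float = 0.05
    exact_counts: bool = False  # zero-noise limit: counts = expected values
    library_size: int = 2_000_000
    n_replicates: int = 3
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        total = sum(self.class_proportions.get(c, 0.0) for c in CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        for c in CLASSES:
            p = self.class_proportions.get(c, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion for {c} outside [0,1]")
        for ct, f in self.resistant_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"resistant_fraction[{ct}] outside [0,1]")
        if not 0.0 <= self.silent_fraction_unchanged <= 1.0:
            raise ValueError("silent_fraction_unchanged outside [0,1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid gene_length_range")


# construction thresholds; identical to the analysis defaults so truth is
# what a noise-free analysis recovers
_TPM_CUT = 1.0
_FC_CUT = 2.0
_PC = 1.0


@dataclass
class ExprTruth:
    """Ground truth emitted by :func:`simulate_expression`.

    ``table`` has one row per gene: ``length``, ``base_class`` (the drawn
    response pattern), ``induced_target_level`` (shared generative NT
    level; NaN for untouched genes) and per cell type ``ct``:
    ``class_{ct}`` (truth class w.r.t. expected TPM),
    ``resistant_{ct}``, ``donor_level_{ct}`` / ``nt_level_{ct}``
    (generative scale) and ``donor_tpm_{ct}`` / ``nt_tpm_{ct}``
    (expected TPM, per-condition columns summing to 10^6).
    """

    table: pd.DataFrame
    cell_types: tuple[str, ...]

    def classes(self, cell_type: str) -> pd.Series:
        return self.table[f"class_{cell_type}"]

    def resistant_set(self, cell_type: str) -> set[str]:
        col = self.table[f"resistant_{cell_type}"]
        return set(self.table.index[col])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cell_types": list(self.cell_types),
            "genes": json.loads(self.table.to_json(orient="index")),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExprTruth":
        payload = json.loads(Path(path).read_text())
        table = pd.DataFrame.from_dict(payload["genes"], orient="index")
        table.index.name = "gene_id"
        return cls(table=table.sort_index(), cell_types=tuple(payload["cell_types"]))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = μ + φμ²; φ=0 → Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    # negative_binomial rejects p == 1 when mean == 0
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def _truth_class(donor_tpm: np.ndarray, nt_tpm: np.ndarray) -> np.ndarray:
    """Response class of expected TPM under the construction thresholds."""
    fc = (nt_tpm + _PC) / (donor_tpm + _PC)
    activated = (donor_tpm < _TPM_CUT) & (nt_tpm >= _TPM_CUT)
    enhanced = ~activated & (donor_tpm >= _TPM_CUT) & (fc >= _FC_CUT)
    repressed = ~activated & ~enhanced & (1.0 / fc >= _FC_CUT)
    out = np.full(donor_tpm.shape, "unchanged", dtype=object)
    out[repressed] = "repressed"
    out[enhanced] = "enhanced"
    out[activated] = "activated"
    return out


def simulate_expression(config: ExprSimConfig) -> tuple[CountMatrix, ExprTruth]:
    """Simulate donor and NT count samples with known response classes.

    Returns the genes × samples :class:`~gvreprog.containers.CountMatrix`
    (donor samples at 0 h plus NT samples at 24 h and 48 h,
    ``n_replicates`` each, one simulated recipient-female id per
    replicate) and the exact :class:`ExprTruth`. Identical config + seed
    gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    cts = tuple(config.cell_types)
    n_ct = len(cts)
    width = max(5, len(str(n)))
    genes = pd.Index([f"g{i:0{width}d}" for i in range(n)], name="gene_id")

    lo, hi = config.gene_length_range
    lengths = pd.Series(rng.integers(lo, hi + 1, size=n), index=genes, name="length")

    # response pattern per gene (shared across cell types; resistance
    # overrides below create the cell-type differences)
    probs = [config.class_proportions.get(c, 0.0) for c in CLASSES]
    base_class = rng.choice(len(CLASSES), size=n, p=probs)

    mu, sd = config.donor_mean_log2
    ct_effect = 2.0 ** rng.normal(0.0, config.celltype_sd_log2, size=(n, n_ct))
    donor = np.zeros((n, n_ct))
    target = np.full(n, np.nan)

    act = base_class == 0
    donor[act] = rng.uniform(0.0, 0.5, size=(act.sum(), n_ct))
    # induced targets span ~2 orders of magnitude, well above the
    # inducibility cut after compositional calibration below
    target[act] = 2.0 ** rng.uniform(3.0, 8.0, size=act.sum())

    enh = base_class == 1
    d_enh = 2.0 ** rng.uniform(1.0, 5.0, size=enh.sum())
    donor[enh] = d_enh[:, None] * ct_effect[enh]
    target[enh] = d_enh * 2.0 ** rng.uniform(2.0, 4.0, size=enh.sum())

    rep = base_class == 2
    d_rep = 2.0 ** rng.uniform(3.0, 8.0, size=rep.sum())
    donor[rep] = d_rep[:, None] * ct_effect[rep]
    target[rep] = d_rep / 2.0 ** rng.uniform(2.0, 4.0, size=rep.sum())

    unc = base_class == 3
    silent = rng.random(size=unc.sum()) < config.silent_fraction_unchanged
    base_unc = np.where(
        silent,
        rng.uniform(0.0, 0.5, size=unc.sum()),
        2.0 ** rng.normal(mu, sd, size=unc.sum()),
    )
    donor[unc] = base_unc[:, None] * np.where(silent[:, None], 1.0, ct_effect[unc])

    # TPM is compositional: calibrate the expressed-regime levels so each
    # condition column totals ~1e6, leaving sub-threshold (silent) draws
    # in absolute TPM units; all drawn fold changes are scale-invariant
    sub = np.zeros((n, n_ct), dtype=bool)
    sub[act] = True
    sub[unc] = silent[:, None]
    induced = ~np.isnan(target)
    nt0 = np.where(induced[:, None], target[:, None], donor)
    sub_nt = sub & ~induced[:, None]
    sub_mass = np.concatenate(
        [(donor * sub).sum(axis=0), (nt0 * sub_nt).sum(axis=0)]
    ).mean()
    expr_mass = np.concatenate(
        [(donor * ~sub).sum(axis=0), (nt0 * ~sub_nt).sum(axis=0)]
    ).mean()
    lam = (1e6 - sub_mass) / expr_mass
    donor = np.where(sub, donor, donor * lam)
    target = target * lam

    # NT generative level: induced genes reach the shared target,
    # unchanged genes keep transcribing at their donor rate
    nt = np.where(induced[:, None], target[:, None], donor)

    # force disjoint per-cell-type resistant sets among inducible genes
    inducible_pool = np.flatnonzero(act | enh)
    pool = rng.permutation(inducible_pool)
    resistant = np.zeros((n, n_ct), dtype=bool)
    offset = 0
    for j, ct in enumerate(cts):
        frac = config.resistant_fraction.get(ct, 0.0)
        k = int(np.floor(frac * inducible_pool.size))
        if offset + k > pool.size:
            raise ValueError("n_genes too small for the requested resistant fractions")
        chosen = pool[offset : offset + k]
        offset += k
        resistant[chosen, j] = True
        nt[chosen, j] = donor[chosen, j]  # no induction in the focal type

    # exact per-condition compositional renormalization
    donor_tpm = donor * (1e6 / donor.sum(axis=0))
    nt_tpm = nt * (1e6 / nt.sum(axis=0))

    class_names = np.array(CLASSES)
    truth = pd.DataFrame(index=genes)
    truth["length"] = lengths
    truth["base_class"] = class_names[base_class]
    truth["induced_target_level"] = target
    for j, ct in enumerate(cts):
        truth[f"class_{ct}"] = _truth_class(donor_tpm[:, j], nt_tpm[:, j])
        truth[f"resistant_{ct}"] = resistant[:, j]
        truth[f"donor_level_{ct}"] = donor[:, j]
        truth[f"nt_level_{ct}"] = nt[:, j]
        truth[f"donor_tpm_{ct}"] = donor_tpm[:, j]
        truth[f"nt_tpm_{ct}"] = nt_tpm[:, j]

    # counts: expected count ∝ TPM × length, scaled to the library size
    length_arr = lengths.to_numpy(dtype=float)
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict[str, object]] = []

    def add_samples(ct: str, condition: str, timepoint: str, tpm_col: np.ndarray) -> None:
        weights = tpm_col * length_arr
        total = weights.sum()
        mean_counts = (
            np.zeros_like(weights) if total == 0 else weights / total * config.library_size
        )
        for r in range(1, config.n_replicates + 1):
            sid = f"{ct}_{condition}_{timepoint}_r{r}"
            if config.exact_counts:
                columns[sid] = mean_counts.copy()
            else:
                columns[sid] = _nb_draw(rng, mean_counts, config.nb_dispersion)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "cell_type": ct,
                    "condition": condition,
                    "timepoint": timepoint,
                    "replicate": r,
                    "female_id": f"F{r}",
                }
            )

    for j, ct in enumerate(cts):
        add_samples(ct, "donor", "0h", donor_tpm[:, j])
    for timepoint in ("24h", "48h"):  # same means, fresh draw
        for j, ct in enumerate(cts):
            add_samples(ct, "NT", timepoint, nt_tpm[:, j])

    counts = pd.DataFrame(columns, index=genes)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    cm = CountMatrix(counts=counts, lengths=lengths, metadata=metadata)
    return cm, ExprTruth(table=truth, cell_types=cts)
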