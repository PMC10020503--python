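"""Seeded synthetic claims bundles for herbal-medicine cohort studies.

The generator emulates the structure of a national claims database as used
by retrospective HIV/AIDS cohort studies: HIV case-defining diagnosis
streams that satisfy (or deliberately fail) the one-inpatient-or-three-
outpatient-visits-within-a-year rule, later neurological diagnoses in four
subtypes, Chinese-herbal-medicine (CHM) prescription streams with planted
pair co-occurrence structure, antiretroviral (ART) dispensings carrying
defined daily doses, and death times drawn from an exponential
proportional-hazards model with a planted CHM effect.

Randomness is organised as one master seed with per-patient substreams
``default_rng([seed, stream, patient_index])`` (stream 1: demographics and
claims, stream 2: death times), so enlarging ``n_patients`` never perturbs
the draws of earlier patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

ART_CLASSES = ("NRTI", "PI", "NNRTI", "INSTI", "COMBINED_ART")
NEURO_SUBTYPES = ("cns_infection", "cognitive", "vasculopathy", "peripheral_neuropathy")
AGE_BANDS = ("lt30", "30to40", "ge40")
CCI_GROUPS = ("0", "1-2", ">=3")

# Representative diagnosis codes the generator emits, chosen so that no code
# collides with another rule's code set (e.g. the CNS-lymphoma rubric 200 is
# never used for CNS infections because it also falls in the malignancy range).
_HIV_CODES = ("042", "043.1", "044.9")
_NEURO_CODES = {
    "cns_infection": ("320.9", "047.9", "054.3", "013.0"),
    "cognitive": ("290.0", "293.0", "294.1", "332.0", "345.1", "780.3"),
    "vasculopathy": ("325", "430", "434.9", "437.0"),
    "peripheral_neuropathy": ("354.0", "355.9", "356.9", "357.0"),
}
_MALIGNANCY_CODES = ("162.9", "155.0", "174.9", "202.8")
_COMORBIDITY_POOL = (
    ("congestive_heart_failure", "428.0", 1),
    ("peripheral_vascular", "440.0", 1),
    ("chronic_pulmonary", "491.0", 1),
    ("rheumatic", "714.0", 1),
    ("peptic_ulcer", "531.0", 1),
    ("mild_liver", "571.5", 1),
    ("diabetes", "250.0", 1),
    ("renal", "585", 2),
)
_OI_CODES = {
    "pjp": "136.3",
    "cmv": "078.5",
    "tb": "010.0",
    "candidiasis": "112.4",
    "cryptococcosis": "117.5",
    "mac": "031.2",
}
# ICD-10 cause-of-death codes per category.
_CAUSE_CODES = {
    "infections_parasites": ("A41.9", "B20", "A09"),
    "circulatory": ("I21.0", "I50.9", "I63.9"),
    "endocrine_metabolic": ("E11.9", "E87.2"),
    "hepatitis_liver": ("B18.2", "K74.6"),
    "respiratory": ("J18.9", "J44.9"),
    "genitourinary": ("N18.9", "N39.0"),
    "neoplasms": ("C34.9", "C22.0"),
    "other": ("R99", "X59", "G93.4"),
}

FILLER_CODE = "OTHER-FILL"


@dataclass(frozen=True)
class HerbProduct:
    """One CHM product in the catalog.

    ``propensity`` is the per-transaction inclusion probability the
    generated transaction stream converges to.
    """

    code: str
    kind: str  # "single_herb" | "formula"
    propensity: float
    daily_dose_g: float
    mean_days: float = 7.0


@dataclass(frozen=True)
class PlantedPair:
    """A product pair whose joint inclusion exceeds independence.

    ``co_boost`` multiplies the independent joint probability; 1 means
    independence (expected lift 1).
    """

    x: str
    y: str
    co_boost: float


@dataclass(frozen=True)
class ChmDaysLaw:
    """Per-year cumulative-CHM-days law.

    A mixture: with probability ``p_below_threshold`` the target is uniform
    on [1, threshold-1] (the exclusion bin); otherwise threshold plus a
    right-skewed lognormal, capped so the stream fits in one year.
    """

    p_below_threshold: float = 0.15
    threshold: int = 14
    lognorm_mean_days: float = 35.0
    lognorm_sd_days: float = 30.0
    cap_days: int = 150


def default_herb_catalog() -> tuple[HerbProduct, ...]:
    """Catalog matching the marginal prescription pattern of a Taiwanese
    HIV/AIDS-with-neurological-disease CHM cohort: the eleven named products
    with transaction propensities equal to their published prescription
    frequencies over 7,376 prescriptions, plus anonymous background formulas
    standing in for the long tail of the market."""
    named = [
        HerbProduct("HQ", "single_herb", 557 / 7376, 1.774),
        HerbProduct("GC", "single_herb", 540 / 7376, 1.042),
        HerbProduct("DaH", "single_herb", 528 / 7376, 1.500),
        HerbProduct("JG", "single_herb", 466 / 7376, 1.010),
        HerbProduct("LDXGT", "formula", 459 / 7376, 10.0),
        HerbProduct("BXXXT", "formula", 407 / 7376, 10.0),
        HerbProduct("HL", "single_herb", 399 / 7376, 0.922),
        HerbProduct("GGT", "formula", 390 / 7376, 10.0),
        HerbProduct("YJT", "single_herb", 324 / 7376, 0.953),
        HerbProduct("SZRT", "formula", 280 / 7376, 11.830),
        HerbProduct("HB", "single_herb", 280 / 7376, 1.004),
    ]
    background = [
        HerbProduct(f"OTHER{i:02d}", "formula", 0.07, 8.0) for i in range(1, 13)
    ]
    return tuple(named + background)


def default_planted_pairs() -> tuple[PlantedPair, ...]:
    """Planted co-prescription structure: the five published pair rules with
    their published lifts as co-occurrence boosts."""
    return (
        PlantedPair("HL", "HQ", 4.81),
        PlantedPair("SZRT", "YJT", 7.81),
        PlantedPair("GC", "HQ", 2.23),
        PlantedPair("JG", "GC", 2.67),
        PlantedPair("HB", "HL", 5.81),
    )


def _default_log_hr() -> dict[str, float]:
    # True conditional effects: the adjusted estimates reported for this
    # population are used as the data-generating truth.
    return {
        "chm_use": math.log(0.30),
        "age_30_40": math.log(1.26),
        "age_ge40": math.log(3.79),
        "female": math.log(2.80),
        "cci_1_2": math.log(1.38),
        "cci_ge3": math.log(1.91),
    }


def _default_cause_probs() -> dict[str, float]:
    # ~51% of deaths fall in infections/parasites + circulatory.
    return {
        "infections_parasites": 0.36,
        "circulatory": 0.15,
        "endocrine_metabolic": 0.07,
        "hepatitis_liver": 0.08,
        "respiratory": 0.08,
        "genitourinary": 0.03,
        "neoplasms": 0.05,
        "other": 0.18,
    }


def _default_oi_probs() -> dict[str, float]:
    return {
        "pjp": 0.12,
        "cmv": 0.045,
        "tb": 0.035,
        "candidiasis": 0.03,
        "cryptococcosis": 0.05,
        "mac": 0.02,
    }


@dataclass
class GeneratorConfig:
    """Full description of the synthetic claims-generating process."""

    n_patients: int = 5000
    study_start: date = date(2008, 1, 1)
    study_end: date = date(2019, 12, 31)
    hiv_onset_years: tuple[int, int] = (2010, 2017)
    p_female: float = 0.045
    age_band_probs: tuple[float, float, float] = (0.33, 0.38, 0.29)
    p_neuro_given_hiv: float = 0.50
    neuro_subtype_probs: tuple[float, float, float, float] = (0.42, 0.34, 0.10, 0.14)
    p_chm_exposed: float = 0.35
    chm_days_distribution: ChmDaysLaw = field(default_factory=ChmDaysLaw)
    baseline_hazard_rate: float = 2.0e-4  # events per person-day
    log_hr: dict[str, float] = field(default_factory=_default_log_hr)
    cause_probs: dict[str, float] = field(default_factory=_default_cause_probs)
    herb_catalog: tuple[HerbProduct, ...] = field(default_factory=default_herb_catalog)
    planted_pairs: tuple[PlantedPair, ...] = field(default_factory=default_planted_pairs)
    seed: int = 0
    # Eligibility / exclusion traffic
    p_fail_hiv_rule: float = 0.02
    p_neuro_before_hiv: float = 0.03
    p_missing_demographics: float = 0.002
    p_malignancy: float = 0.01
    # Covariate structure
    cci_group_probs: tuple[float, float, float] = (0.77, 0.18, 0.05)
    chm_odds_by_age: tuple[float, float, float] = (1.0, 0.65, 0.45)
    chm_odds_by_cci: tuple[float, float, float] = (1.0, 1.35, 1.60)
    secondary_subtype_prob: float = 0.15
    oi_probs: dict[str, float] = field(default_factory=_default_oi_probs)
    # Index-duration (HIV -> neuro) law: lognormal matched to mean 786 /
    # SD 804 days, truncated below at 60 days and above to leave room for
    # the one-year CHM window before study end.
    index_gap_mean_days: float = 786.0
    index_gap_sd_days: float = 804.0
    index_gap_min_days: int = 60

    def validate(self) -> None:
        def _prob(name: str, v: float) -> None:
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be a probability, got {v}")

        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.study_start >= self.study_end:
            raise ConfigurationError("study_start must precede study_end")
        _prob("p_female", self.p_female)
        _prob("p_neuro_given_hiv", self.p_neuro_given_hiv)
        _prob("p_chm_exposed", self.p_chm_exposed)
        _prob("p_fail_hiv_rule", self.p_fail_hiv_rule)
        _prob("p_neuro_before_hiv", self.p_neuro_before_hiv)
        _prob("p_missing_demographics", self.p_missing_demographics)
        _prob("p_malignancy", self.p_malignancy)
        for name, vec, k in (
            ("age_band_probs", self.age_band_probs, 3),
            ("neuro_subtype_probs", self.neuro_subtype_probs, 4),
            ("cci_group_probs", self.cci_group_probs, 3),
        ):
            if len(vec) != k or abs(sum(vec) - 1.0) > 1e-12 or min(vec) < 0:
                raise ConfigurationError(f"{name} must be a {k}-vector summing to 1")
        if abs(sum(self.cause_probs.values()) - 1.0) > 1e-12:
            raise ConfigurationError("cause_probs must sum to 1")
        if set(self.cause_probs) - set(_CAUSE_CODES):
            raise ConfigurationError("cause_probs has unknown category keys")
        if self.baseline_hazard_rate <= 0:
            raise ConfigurationError("baseline_hazard_rate must be > 0")
        missing = set(_default_log_hr()) - set(self.log_hr)
        if missing:
            raise ConfigurationError(f"log_hr missing keys: {sorted(missing)}")
        if not self.herb_catalog:
            raise ConfigurationError("herb_catalog must be non-empty")
        codes = [p.code for p in self.herb_catalog]
        if len(set(codes)) != len(codes):
            raise ConfigurationError("herb_catalog has duplicate product codes")
        for p in self.herb_catalog:
            if not (0.0 < p.propensity <= 1.0):
                raise ConfigurationError(
                    f"herb_catalog[{p.code}].propensity must lie in (0, 1]"
                )
            if p.daily_dose_g <= 0 or p.mean_days <= 0:
                raise ConfigurationError(
                    f"herb_catalog[{p.code}]: dose and days must be positive"
                )
        known = set(codes)
        for pair in self.planted_pairs:
            if pair.x not in known or pair.y not in known:
                raise ConfigurationError(
                    f"planted pair ({pair.x}, {pair.y}) not in herb_catalog"
                )
            if pair.co_boost <= 0:
                raise ConfigurationError("co_boost must be strictly positive")
        law = self.chm_days_distribution
        _prob("chm_days_distribution.p_below_threshold", law.p_below_threshold)
        if law.threshold < 2 or law.cap_days < law.threshold:
            raise ConfigurationError("chm_days_distribution thresholds inconsistent")


@dataclass
class ClaimsBundle:
    """The four raw claims tables plus provenance.

    ``truth`` carries the generator's per-patient ground truth (exposure,
    planted exclusion label, covariates); it is kept in memory for testing
    and is not part of the on-disk schema.
    """

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    deaths: pd.DataFrame
    provenance: dict
    truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Transaction sampling with planted pair structure


class TransactionSampler:
    """Draws per-transaction product sets honouring catalog marginals and
    planted joint boosts.

    For each planted pair a joint-inclusion probability q is solved by fixed
    point so that the overall joint probability equals
    ``min(co_boost * p_x * p_y, 0.95 * min(p_x, p_y))``; the remaining
    marginal mass is drawn independently.  Transactions that draw empty are
    padded with one background product (a catalog product not involved in
    any planted pair, or a reserved ``OTHER-FILL`` item) so that every
    transaction is non-empty while planted lifts and named marginals stay at
    their configured values.
    """

    def __init__(
        self,
        catalog: tuple[HerbProduct, ...],
        planted_pairs: tuple[PlantedPair, ...],
    ) -> None:
        if not catalog:
            raise ConfigurationError("herb_catalog must be non-empty")
        self.catalog = tuple(catalog)
        self.codes = [p.code for p in catalog]
        self.by_code = {p.code: p for p in catalog}
        for pair in planted_pairs:
            if pair.x not in self.by_code or pair.y not in self.by_code:
                raise ConfigurationError(
                    f"planted pair ({pair.x}, {pair.y}) not in herb_catalog"
                )
        self.pairs = tuple(planted_pairs)
        self._solve()

    def _solve(self) -> None:
        p = {c: self.by_code[c].propensity for c in self.codes}
        pairs = self.pairs
        targets = [
            min(pr.co_boost * p[pr.x] * p[pr.y], 0.95 * min(p[pr.x], p[pr.y]))
            for pr in pairs
        ]
        q = [min(t, 1.0) for t in targets]
        idx_pairs = {c: [j for j, pr in enumerate(pairs) if c in (pr.x, pr.y)]
                     for c in self.codes}
        r = dict(p)
        for _ in range(200):
            # residual inclusion so that total marginal equals p
            s = {}
            for c in self.codes:
                keep = 1.0
                for j in idx_pairs[c]:
                    keep *= 1.0 - q[j]
                s[c] = 1.0 - keep
            r = {
                c: 0.0 if s[c] >= p[c] else (p[c] - s[c]) / (1.0 - s[c])
                for c in self.codes
            }
            q_new = []
            for j, pr in enumerate(pairs):
                # inclusion of each endpoint NOT via pair j
                ux, uy = 1.0, 1.0
                for jj in idx_pairs[pr.x]:
                    if jj != j:
                        ux *= 1.0 - q[jj]
                ux = 1.0 - (1.0 - r[pr.x]) * ux
                for jj in idx_pairs[pr.y]:
                    if jj != j:
                        uy *= 1.0 - q[jj]
                uy = 1.0 - (1.0 - r[pr.y]) * uy
                other = ux * uy
                if other >= targets[j]:
                    q_new.append(0.0)
                else:
                    q_new.append((targets[j] - other) / (1.0 - other))
            if max((abs(a - b) for a, b in zip(q, q_new)), default=0.0) < 1e-12:
                q = q_new
                break
            q = q_new
        self.q = np.asarray(q)
        self.resid = np.asarray([r[c] for c in self.codes])
        planted_codes = {c for pr in pairs for c in (pr.x, pr.y)}
        bg = [c for c in self.codes if c not in planted_codes]
        if bg:
            w = np.asarray([p[c] for c in bg], dtype=float)
            self._bg_codes = bg
            self._bg_probs = w / w.sum()
        else:
            self._bg_codes = [FILLER_CODE]
            self._bg_probs = np.asarray([1.0])

    def sample(self, rng: np.random.Generator, m: int) -> list[tuple[str, ...]]:
        """Draw ``m`` non-empty product sets."""
        if m <= 0:
            return []
        n_prod = len(self.codes)
        member = rng.random((m, n_prod)) < self.resid[None, :]
        if len(self.pairs):
            hit = rng.random((m, len(self.pairs))) < self.q[None, :]
            col = {c: k for k, c in enumerate(self.codes)}
            for j, pr in enumerate(self.pairs):
                member[hit[:, j], col[pr.x]] = True
                member[hit[:, j], col[pr.y]] = True
        empty = ~member.any(axis=1)
        pad = rng.choice(len(self._bg_codes), size=int(empty.sum()), p=self._bg_probs)
        out: list[tuple[str, ...]] = []
        codes = np.asarray(self.codes, dtype=object)
        pad_iter = iter(pad)
        for i in range(m):
            if empty[i]:
                out.append((self._bg_codes[next(pad_iter)],))
            else:
                out.append(tuple(codes[member[i]]))
        return out

    def product(self, code: str) -> HerbProduct:
        if code == FILLER_CODE:
            return HerbProduct(FILLER_CODE, "formula", 1.0, 8.0)
        return self.by_code[code]


def generate_transactions_only(
    catalog: tuple[HerbProduct, ...],
    planted_pairs: tuple[PlantedPair, ...],
    n_transactions: int,
    seed: int,
) -> pd.DataFrame:
    """Emit a CHM prescription table of ``n_transactions`` patient-day
    transactions with the configured marginal/joint structure.

    A lightweight fixture generator for rule-mining: one synthetic patient
    per transaction, all on distinct dates.
    """
    if n_transactions < 1:
        raise ConfigurationError("n_transactions must be >= 1")
    sampler = TransactionSampler(catalog, planted_pairs)
    rng = np.random.default_rng([int(seed), 0])
    sets = sampler.sample(rng, n_transactions)
    base = date(2015, 1, 1)
    rows = []
    for i, prods in enumerate(sets):
        d = (base + timedelta(days=i % 3650)).isoformat()
        pid = f"T{i:07d}"
        for code in prods:
            prod = sampler.product(code)
            rows.append(
                (pid, d, "CHM", code, prod.kind, int(round(prod.mean_days)),
                 prod.daily_dose_g, np.nan)
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "date", "class", "product_code", "product_kind",
                 "days", "daily_dose_g", "ddd_amount"],
    )


# ---------------------------------------------------------------------------
# Helpers


def chm_index_date(
    dates: list[date], days: list[int], threshold: int = 14
) -> date | None:
    """The day after the prescription-day on which the running cumulative
    CHM days first reach ``threshold``; None if never reached.

    Rows are processed in date order; same-day rows accumulate together.
    """
    order = np.argsort(np.asarray(dates, dtype="datetime64[D]"), kind="stable")
    total = 0
    for k in order:
        total += int(days[k])
        if total >= threshold:
            return dates[k] + timedelta(days=1)
    return None


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_date(rng: np.random.Generator, lo: date, hi: date) -> date:
    span = (hi - lo).days
    return lo + timedelta(days=int(rng.integers(0, span + 1)))


# ---------------------------------------------------------------------------
# Bundle generation


def generate_bundle(config: GeneratorConfig) -> ClaimsBundle:
    """Generate a synthetic claims bundle. Deterministic given the seed."""
    config.validate()
    cfg = config
    sampler = TransactionSampler(cfg.herb_catalog, cfg.planted_pairs)
    law = cfg.chm_days_distribution
    gap_mu, gap_sigma = _lognormal_params(cfg.index_gap_mean_days, cfg.index_gap_sd_days)
    onset_lo = date(cfg.hiv_onset_years[0], 1, 1)
    onset_hi = date(cfg.hiv_onset_years[1], 12, 31)
    latest_neuro = cfg.study_end - timedelta(days=366)

    pat_rows: list[tuple] = []
    dx_rows: list[tuple] = []
    rx_rows: list[tuple] = []
    plans: list[dict] = []

    cause_labels = list(cfg.cause_probs)
    cause_p = np.asarray([cfg.cause_probs[c] for c in cause_labels])

    for i in range(cfg.n_patients):
        rng = np.random.default_rng([int(cfg.seed), 1, i])
        pid = f"P{i:07d}"
        female = bool(rng.random() < cfg.p_female)
        band = int(rng.choice(3, p=np.asarray(cfg.age_band_probs)))
        eligible = rng.random() >= cfg.p_fail_hiv_rule
        hiv_date = _draw_date(rng, onset_lo, onset_hi)

        plan: dict = {
            "patient_id": pid,
            "female": female,
            "age_band": band,
            "eligible_hiv": eligible,
            "hiv_date": hiv_date,
            "neuro": False,
            "neuro_before": False,
            "missing_demo": False,
            "malignancy": False,
            "exposed": False,
            "chm_target_days": 0,
            "chm_user": False,
            "index_date": None,
            "neuro_date": None,
            "cci_group": 0,
            "cci_score": 0.0,
            "last_chm_date": None,
        }

        # HIV diagnosis stream
        if eligible:
            if rng.random() < 0.3:
                dx_rows.append((pid, hiv_date, "inpatient", 9,
                                _HIV_CODES[int(rng.integers(0, 3))]))
            else:
                for off in (0, 3, 6):
                    dx_rows.append((pid, hiv_date + timedelta(days=off),
                                    "outpatient", 9,
                                    _HIV_CODES[int(rng.integers(0, 3))]))
        else:
            for off in (0, 200):
                dx_rows.append((pid, hiv_date + timedelta(days=off), "outpatient",
                                9, _HIV_CODES[int(rng.integers(0, 3))]))

        # Comorbidities strictly before HIV diagnosis
        grp = int(rng.choice(3, p=np.asarray(cfg.cci_group_probs)))
        plan["cci_group"] = grp
        if grp > 0:
            n_cat = int(rng.integers(1, 3)) if grp == 1 else int(rng.integers(3, 5))
            n_cat = min(n_cat, len(_COMORBIDITY_POOL))
            picks = rng.choice(len(_COMORBIDITY_POOL), size=n_cat, replace=False)
            score = 0
            for k in picks:
                cat, code, weight = _COMORBIDITY_POOL[int(k)]
                score += weight
                dmin = max(cfg.study_start, hiv_date - timedelta(days=700))
                dmax = hiv_date - timedelta(days=30)
                if dmin >= dmax:
                    dmin = dmax - timedelta(days=1)
                dx_rows.append((pid, _draw_date(rng, dmin, dmax), "outpatient", 9, code))
            plan["cci_score"] = float(score)

        if eligible and rng.random() < cfg.p_neuro_given_hiv:
            plan["neuro"] = True
            plan["neuro_before"] = bool(rng.random() < cfg.p_neuro_before_hiv)
            if plan["neuro_before"]:
                lo = max(cfg.study_start, hiv_date - timedelta(days=400))
                hi = hiv_date - timedelta(days=60)
                if lo >= hi:
                    lo = hi - timedelta(days=1)
                neuro_date = _draw_date(rng, lo, hi)
            else:
                gap = max(
                    cfg.index_gap_min_days, int(rng.lognormal(gap_mu, gap_sigma))
                )
                neuro_date = hiv_date + timedelta(days=gap)
                if neuro_date > latest_neuro:
                    neuro_date = latest_neuro
            plan["neuro_date"] = neuro_date
            subtype = NEURO_SUBTYPES[
                int(rng.choice(4, p=np.asarray(cfg.neuro_subtype_probs)))
            ]
            plan["subtype"] = subtype
            code = _NEURO_CODES[subtype][int(rng.integers(0, len(_NEURO_CODES[subtype])))]
            for off in (0, 3, 6):
                dx_rows.append((pid, neuro_date + timedelta(days=off),
                                "outpatient", 9, code))
            if not plan["neuro_before"] and rng.random() < cfg.secondary_subtype_prob:
                others = [s for s in NEURO_SUBTYPES if s != subtype]
                sub2 = others[int(rng.integers(0, len(others)))]
                code2 = _NEURO_CODES[sub2][0]
                base2 = neuro_date + timedelta(days=int(rng.integers(30, 90)))
                for off in (0, 3, 6):
                    dx_rows.append((pid, base2 + timedelta(days=off),
                                    "outpatient", 9, code2))

            plan["missing_demo"] = bool(rng.random() < cfg.p_missing_demographics)
            plan["malignancy"] = bool(rng.random() < cfg.p_malignancy)
            if plan["malignancy"] and not plan["neuro_before"]:
                mcode = _MALIGNANCY_CODES[int(rng.integers(0, len(_MALIGNANCY_CODES)))]
                dx_rows.append((pid, neuro_date + timedelta(days=1),
                                "outpatient", 9, mcode))

            # Opportunistic infections between HIV and neuro diagnosis
            if not plan["neuro_before"]:
                gap_days = (neuro_date - hiv_date).days
                for oi, p_oi in cfg.oi_probs.items():
                    if rng.random() < p_oi:
                        off = int(rng.integers(7, max(8, gap_days))) if gap_days > 8 else 1
                        dx_rows.append((pid, hiv_date + timedelta(days=off),
                                        "outpatient", 9, _OI_CODES[oi]))

            # CHM exposure with mild confounding by age and comorbidity
            if not plan["neuro_before"]:
                p0 = cfg.p_chm_exposed
                odds = (p0 / (1 - p0)) * cfg.chm_odds_by_age[band] \
                    * cfg.chm_odds_by_cci[grp]
                p_exp = odds / (1 + odds)
                plan["exposed"] = bool(rng.random() < p_exp)
            if plan["exposed"]:
                if rng.random() < law.p_below_threshold:
                    target = int(rng.integers(1, law.threshold))
                else:
                    mu, sig = _lognormal_params(
                        law.lognorm_mean_days, law.lognorm_sd_days
                    )
                    target = law.threshold + int(rng.lognormal(mu, sig))
                    target = min(target, law.cap_days)
                plan["chm_target_days"] = target
                low = target < law.threshold
                d = neuro_date + timedelta(days=int(rng.integers(7, 31)))
                total = 0
                chm_dates: list[date] = []
                chm_days: list[int] = []
                while total < target and d <= neuro_date + timedelta(days=358):
                    prods = sampler.sample(rng, 1)[0]
                    for code_ in prods:
                        prod = sampler.product(code_)
                        row_days = max(1, int(rng.poisson(prod.mean_days)))
                        if low:
                            row_days = min(row_days, target - total)
                            if row_days == 0:
                                break
                        rx_rows.append((pid, d, "CHM", code_, prod.kind, row_days,
                                        prod.daily_dose_g, np.nan))
                        chm_dates.append(d)
                        chm_days.append(row_days)
                        total += row_days
                        if total >= target:
                            break
                    d = d + timedelta(days=int(rng.integers(3, 15)))
                if not low and total < law.threshold:
                    # numeric guard; essentially unreachable under defaults
                    pad_d = neuro_date + timedelta(days=350)
                    prod = sampler.product(sampler.codes[0])
                    need = law.threshold - total
                    rx_rows.append((pid, pad_d, "CHM", prod.code, prod.kind, need,
                                    prod.daily_dose_g, np.nan))
                    chm_dates.append(pad_d)
                    chm_days.append(need)
                    total += need
                plan["chm_user"] = total >= law.threshold
                plan["last_chm_date"] = max(chm_dates) if chm_dates else None
                if plan["chm_user"]:
                    plan["index_date"] = chm_index_date(
                        chm_dates, chm_days, law.threshold
                    )

            # ART dispensings between HIV and neuro diagnosis
            gap_days = max(30, (neuro_date - hiv_date).days) if not plan["neuro_before"] \
                else 200
            n_art = max(1, int(rng.poisson(gap_days / 45)))
            for _ in range(n_art):
                cls = ART_CLASSES[int(rng.choice(5, p=np.asarray(
                    [0.35, 0.25, 0.15, 0.10, 0.15])))]
                off = int(rng.integers(7, max(8, gap_days)))
                rx_rows.append((pid, hiv_date + timedelta(days=off), cls,
                                f"ART-{cls}", "art", 30, np.nan, 30.0))
        elif eligible:
            # HIV without neurological disease: ART only
            n_art = max(1, int(rng.poisson(6)))
            for _ in range(n_art):
                cls = ART_CLASSES[int(rng.choice(5, p=np.asarray(
                    [0.35, 0.25, 0.15, 0.10, 0.15])))]
                off = int(rng.integers(7, 600))
                d = hiv_date + timedelta(days=off)
                if d <= cfg.study_end:
                    rx_rows.append((pid, d, cls, f"ART-{cls}", "art", 30, np.nan, 30.0))

        # Demographics table row (blanked when planted missing)
        age_lo = (20.1, 30.1, 40.1)[band]
        age_hi = (29.9, 39.9, 64.9)[band]
        age = float(rng.uniform(age_lo, age_hi))
        ref = plan["neuro_date"] or hiv_date
        birth = ref - timedelta(days=int(round(age * 365.25)))
        sex = "F" if female else "M"
        if plan["missing_demo"]:
            if rng.random() < 0.5:
                sex = ""
            else:
                birth = None
        pat_rows.append((pid, sex, birth))
        plans.append(plan)

    # Landmark for non-users: the lower median of user lags (index - neuro),
    # computed over users not planted for exclusion, the same set the cohort
    # builder retains.
    lags = sorted(
        (p["index_date"] - p["neuro_date"]).days
        for p in plans
        if p["chm_user"] and not (p["neuro_before"] or p["missing_demo"]
                                  or p["malignancy"])
    )
    median_lag = lags[(len(lags) - 1) // 2] if lags else 30

    # Death pass (separate substream so the claims pass stays stable)
    death_rows: list[tuple] = []
    truth_rows: list[dict] = []
    log_hr = cfg.log_hr
    for i, plan in enumerate(plans):
        rng = np.random.default_rng([int(cfg.seed), 2, i])
        lp = 0.0
        if plan["chm_user"]:
            lp += log_hr["chm_use"]
        if plan["age_band"] == 1:
            lp += log_hr["age_30_40"]
        elif plan["age_band"] == 2:
            lp += log_hr["age_ge40"]
        if plan["female"]:
            lp += log_hr["female"]
        if plan["cci_group"] == 1:
            lp += log_hr["cci_1_2"]
        elif plan["cci_group"] == 2:
            lp += log_hr["cci_ge3"]
        rate = cfg.baseline_hazard_rate * math.exp(lp)
        t_days = int(math.ceil(rng.exponential(1.0 / rate)))
        t_days = max(1, t_days)
        if plan["neuro"] and not plan["neuro_before"]:
            if plan["chm_user"]:
                t0 = plan["index_date"]
            elif plan["exposed"]:
                t0 = max(plan["neuro_date"] + timedelta(days=median_lag),
                         (plan["last_chm_date"] or plan["neuro_date"])
                         + timedelta(days=1))
            else:
                t0 = plan["neuro_date"] + timedelta(days=median_lag)
        else:
            t0 = plan["hiv_date"] + timedelta(days=400)
        death_date = t0 + timedelta(days=t_days)
        died = death_date <= cfg.study_end
        if died:
            cat = cause_labels[int(rng.choice(len(cause_labels), p=cause_p))]
            codes = _CAUSE_CODES[cat]
            death_rows.append((plan["patient_id"], death_date,
                               codes[int(rng.integers(0, len(codes)))]))
        truth_rows.append({
            "patient_id": plan["patient_id"],
            "eligible_hiv": plan["eligible_hiv"],
            "neuro": plan["neuro"],
            "neuro_before": plan["neuro_before"],
            "missing_demo": plan["missing_demo"],
            "malignancy": plan["malignancy"],
            "exposed": plan["exposed"],
            "chm_user": plan["chm_user"],
            "chm_target_days": plan["chm_target_days"],
            "age_band": AGE_BANDS[plan["age_band"]],
            "female": plan["female"],
            "cci_group": CCI_GROUPS[plan["cci_group"]],
            "cci_score": plan["cci_score"],
            "hiv_date": plan["hiv_date"],
            "neuro_date": plan["neuro_date"],
            "index_date": plan["index_date"] if plan["chm_user"] else (
                plan["neuro_date"] + timedelta(days=median_lag)
                if plan["neuro"] and not plan["neuro_before"] else None),
            "death_date": death_date if died else None,
        })

    patients = pd.DataFrame(pat_rows, columns=["id", "sex", "birth_date"])
    diagnoses = pd.DataFrame(
        dx_rows, columns=["patient_id", "date", "setting", "icd_version", "code"]
    )
    prescriptions = pd.DataFrame(
        rx_rows,
        columns=["patient_id", "date", "class", "product_code", "product_kind",
                 "days", "daily_dose_g", "ddd_amount"],
    )
    deaths = pd.DataFrame(death_rows, columns=["patient_id", "date", "cause_code"])
    deaths["icd_version"] = 10
    truth = pd.DataFrame(truth_rows)

    # Drop claims dated after death
    if len(deaths):
        dmap = dict(zip(deaths["patient_id"], deaths["date"]))
        for df in (diagnoses, prescriptions):
            dd = df["patient_id"].map(dmap)
            keep = dd.isna() | (df["date"] <= dd)
            df.drop(index=df.index[~keep], inplace=True)
            df.reset_index(drop=True, inplace=True)

    for df in (diagnoses, prescriptions, deaths):
        df["date"] = pd.to_datetime(df["date"])
    patients["birth_date"] = pd.to_datetime(patients["birth_date"])
    diagnoses.sort_values(["patient_id", "date", "code"], inplace=True,
                          kind="stable", ignore_index=True)
    prescriptions.sort_values(["patient_id", "date", "product_code"], inplace=True,
                              kind="stable", ignore_index=True)
    deaths.sort_values("patient_id", inplace=True, kind="stable", ignore_index=True)

    t = truth
    first_bin = np.select(
        [
            t["neuro_before"] & t["neuro"],
            t["neuro"] & ~t["neuro_before"] & t["missing_demo"],
            t["neuro"] & ~t["neuro_before"] & ~t["missing_demo"]
            & t["exposed"] & ~t["chm_user"],
            t["neuro"] & ~t["neuro_before"] & ~t["missing_demo"]
            & ~(t["exposed"] & ~t["chm_user"]) & t["malignancy"],
        ],
        ["neuro_before_hiv", "missing_demographics", "low_chm", "malignancy"],
        default="",
    )
    truth["planted_exclusion"] = first_bin
    in_frame = t["eligible_hiv"] & t["neuro"]
    planted = {
        "neuro_before_hiv": int(((first_bin == "neuro_before_hiv") & in_frame).sum()),
        "missing_demographics": int(
            ((first_bin == "missing_demographics") & in_frame).sum()),
        "low_chm": int(((first_bin == "low_chm") & in_frame).sum()),
        "malignancy": int(((first_bin == "malignancy") & in_frame).sum()),
        "retained": int(((first_bin == "") & in_frame).sum()),
        "median_user_lag_days": int(median_lag),
    }

    provenance = {
        "generator": "herbsurv.synthetic_claims",
        "seed": int(cfg.seed),
        "n_patients": int(cfg.n_patients),
        "config": _config_echo(cfg),
        "planted": planted,
    }
    return ClaimsBundle(patients, diagnoses, prescriptions, deaths, provenance, truth)


def _config_echo(cfg: GeneratorConfig) -> dict:
    echo = asdict(cfg)
    echo["study_start"] = cfg.study_start.isoformat()
    echo["study_end"] = cfg.study_end.isoformat()
    return echo


# ---------------------------------------------------------------------------
# On-disk round trip


_REQUIRED_COLUMNS = {
    "patients": ["id", "sex", "birth_date"],
    "diagnoses": ["patient_id", "date", "setting", "icd_version", "code"],
    "prescriptions": ["patient_id", "date", "class", "product_code",
                      "product_kind", "days", "daily_dose_g", "ddd_amount"],
    "deaths": ["patient_id", "date", "cause_code", "icd_version"],
}


def validate_bundle(bundle: ClaimsBundle) -> None:
    """Check referential and temporal invariants; raise DataError on violation."""
    for name, cols in _REQUIRED_COLUMNS.items():
        df = getattr(bundle, name)
        missing = set(cols) - set(df.columns)
        if missing:
            raise DataError(f"table {name} missing columns {sorted(missing)}")
    ids = bundle.patients["id"]
    if ids.duplicated().any():
        raise DataError("patients table has duplicate ids")
    known = set(ids)
    for name in ("diagnoses", "prescriptions", "deaths"):
        df = getattr(bundle, name)
        bad = ~df["patient_id"].isin(known)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(f"table {name} row {row}: unknown patient_id")
    if bundle.deaths["patient_id"].duplicated().any():
        raise DataError("more than one death row for a patient")
    rx = bundle.prescriptions
    if (rx["days"] < 1).any():
        raise DataError("prescriptions: days must be >= 1")
    chm = rx[rx["class"] == "CHM"]
    if not (chm["daily_dose_g"] > 0).all():
        raise DataError("prescriptions: CHM rows need daily_dose_g > 0")
    art = rx[rx["product_kind"] == "art"]
    if len(art) and not (art["ddd_amount"] > 0).all():
        raise DataError("prescriptions: ART rows need ddd_amount > 0")
    if len(bundle.deaths):
        dmap = dict(zip(bundle.deaths["patient_id"], bundle.deaths["date"]))
        for name in ("diagnoses", "prescriptions"):
            df = getattr(bundle, name)
            dd = df["patient_id"].map(dmap)
            if ((~dd.isna()) & (df["date"] > dd)).any():
                raise DataError(f"table {name}: event dated after the patient's death")


def write_bundle(bundle: ClaimsBundle, outdir) -> dict[str, str]:
    """Write the four tables as UTF-8 CSV with ISO dates plus a JSON
    provenance sidecar; returns the file map."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name in ("patients", "diagnoses", "prescriptions", "deaths"):
        df = getattr(bundle, name).copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        files[name] = str(path)
    prov = outdir / "provenance.json"
    with open(prov, "w", encoding="utf-8") as fh:
        json.dump(bundle.provenance, fh, indent=2, default=str)
    files["provenance"] = str(prov)
    return files


def read_bundle(indir) -> ClaimsBundle:
    """Read a bundle written by :func:`write_bundle`, validating the schema."""
    import json
    from pathlib import Path

    indir = Path(indir)
    frames = {}
    for name, cols in _REQUIRED_COLUMNS.items():
        path = indir / f"{name}.csv"
        if not path.exists():
            raise DataError(f"missing table file {path}")
        df = pd.read_csv(path, dtype={"code": str, "cause_code": str})
        missing = set(cols) - set(df.columns)
        if missing:
            raise DataError(f"table {name} missing columns {sorted(missing)}")
        for col in ("date", "birth_date"):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col], format="ISO8601")
        if "sex" in df.columns:
            df["sex"] = df["sex"].fillna("")
        frames[name] = df
    prov_path = indir / "provenance.json"
    provenance = {}
    if prov_path.exists():
        with open(prov_path, encoding="utf-8") as fh:
            provenance = json.load(fh)
    bundle = ClaimsBundle(frames["patients"], frames["diagnoses"],
                          frames["prescriptions"], frames["deaths"], provenance)
    validate_bundle(bundle)
    return bundle


# ---------------------------------------------------------------------------
# Direct survival simulation (for calibration studies)


def simulate_survival_frame(
    n: int,
    log_hr: dict[str, float] | None = None,
    baseline_hazard_rate: float = 2.0e-4,
    admin_censor_days: float = 3000.0,
    p_exposed: float = 0.33,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw an analysis-ready survival frame directly from the exponential
    proportional-hazards law the bundle generator uses, without the claims
    layer.  Covariates: chm (Bernoulli), age band, female, CCI group, drawn
    from the generator's default marginals and independent of each other.
    """
    rng = np.random.default_rng(seed)
    hr = dict(_default_log_hr())
    if log_hr:
        hr.update(log_hr)
    chm = rng.random(n) < p_exposed
    band = rng.choice(3, size=n, p=[0.33, 0.38, 0.29])
    female = rng.random(n) < 0.045
    cci = rng.choice(3, size=n, p=[0.77, 0.18, 0.05])
    lp = (
        chm * hr["chm_use"]
        + (band == 1) * hr["age_30_40"]
        + (band == 2) * hr["age_ge40"]
        + female * hr["female"]
        + (cci == 1) * hr["cci_1_2"]
        + (cci == 2) * hr["cci_ge3"]
    )
    t = rng.exponential(1.0 / (baseline_hazard_rate * np.exp(lp)))
    censor = rng.uniform(admin_censor_days * 0.4, admin_censor_days, size=n)
    time = np.minimum(t, censor)
    event = t <= censor
    return pd.DataFrame({
        "time": np.maximum(1.0, np.ceil(time)),
        "event": event,
        "chm": chm.astype(int),
        "age_30_40": (band == 1).astype(int),
        "age_ge40": (band == 2).astype(int),
        "female": female.astype(int),
        "cci_1_2": (cci == 1).astype(int),
        "cci_ge3": (cci == 2).astype(int),
    })
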