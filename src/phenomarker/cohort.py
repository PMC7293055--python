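"""Synthetic smartphone-sensing cohort generator.

Emulates the statistical structure of a two-week passive-sensing study of
social anxiety in n≈59 undergraduates: 1 Hz accelerometer magnitude with a
severity-dependent gait oscillation near a 6.35 s period, call/text event
logs whose timing shifts with severity, and baseline self-reports (SIAS,
DASS-21 depression, PANAS positive/negative affect) with missing values.

Every participant carries a latent standardized severity ``z`` ~ N(0, 1).
Observable signals are tied to ``z`` through configurable slopes so that
downstream biomarkers are identifiable by construction:

* SIAS = round(29.1 + 9.4 z), clipped to [0, 80];
* gait-band oscillation amplitude = max(0, a0 + amplitude_slope * z)
  (negative slope: less anxious participants oscillate with larger
  amplitude);
* per-contact event rates scale as exp(comm_rate_slope * z);
* reply latencies are log-normal with log-mean shifted by
  reply_delay_slope * z;
* missed-call probability is logistic in z with slope missed_call_slope;
* DASS/PANAS scores are drawn from a one-factor Gaussian model with the
  configured target correlations to ``z``, then discretized; missingness
  is applied completely at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "CommEvent",
    "ParticipantRecord",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

SIAS_MEAN = 29.1
SIAS_SD = 9.4

ACCEL_FILE = "accel.csv"
COMM_FILE = "comm.csv"
SURVEY_FILE = "surveys.csv"


class CohortConfigError(ValueError):
    """Raised when a CohortConfig fails validation."""


class CohortParseError(ValueError):
    """Raised when on-disk cohort files violate the schema."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions the generator emulates:
    59 participants observed for a mean of 16.41 days (SD 2.69), a gait
    oscillation at a 6.35 s period whose amplitude falls with severity,
    and discriminant-measure correlations of moderate size. Accelerometer
    output is capped at ``accel_days_cap`` days per participant unless
    ``accel_full_length`` is set; communication streams always span the
    full observation window.
    """

    n_participants: int = 59
    duration_days_mean: float = 16.41
    duration_days_sd: float = 2.69
    accel_rate: float = 1.0          # samples per second
    accel_days_cap: float = 1.0      # days of accelerometer emitted by default
    accel_full_length: bool = False
    gait_period_s: float = 6.35
    gait_amplitude_base: float = 0.6  # m/s^2 at z = 0
    amplitude_slope: float = -0.2     # m/s^2 per severity SD (negative)
    active_fraction: float = 0.25     # share of wear time spent in movement bouts
    comm_rate_base: float = 18.0      # expected events/day at z = 0
    comm_rate_slope: float = -0.15    # log-rate change per severity SD
    reply_delay_slope: float = 0.4    # log-latency change per severity SD
    missed_call_slope: float = 0.5    # logit change per severity SD
    variance_compensation: bool = False  # hold total bout variance constant
    bout_var_target: float | None = None  # total in-bout variance when compensating
    gait_noise_ar: float = 0.0            # AR(1) coefficient of in-bout noise
    gait_noise_ar_jitter: float = 0.0     # per-participant AR spread (uniform)
    gait_phase_jitter: float = 0.0        # per-sample gait phase random walk (rad)
    target_corr_depression: float = 0.45
    target_corr_na: float = 0.45
    target_corr_pa: float = -0.30
    missing_rate_dep: float = 0.05
    missing_rate_na: float = 0.14
    missing_rate_pa: float = 0.14
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise CohortConfigError("n_participants must be positive")
        if self.duration_days_mean <= 0 or self.duration_days_sd < 0:
            raise CohortConfigError("duration must be strictly positive")
        if self.accel_rate <= 0 or self.accel_days_cap <= 0:
            raise CohortConfigError("accel_rate and accel_days_cap must be positive")
        if self.gait_period_s <= 0:
            raise CohortConfigError("gait_period_s must be positive")
        if not 0 < self.active_fraction <= 1:
            raise CohortConfigError("active_fraction must lie in (0, 1]")
        if self.comm_rate_base < 0:
            raise CohortConfigError("comm_rate_base must be non-negative")
        for name in ("missing_rate_dep", "missing_rate_na", "missing_rate_pa"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise CohortConfigError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.gait_noise_ar < 1:
            raise CohortConfigError("gait_noise_ar must lie in [0, 1)")
        if self.gait_noise_ar_jitter < 0 or self.gait_phase_jitter < 0:
            raise CohortConfigError("jitter parameters must be non-negative")
        if self.gait_noise_ar + self.gait_noise_ar_jitter >= 1:
            raise CohortConfigError("gait_noise_ar + jitter must stay below 1")
        rhos = {
            "target_corr_depression": self.target_corr_depression,
            "target_corr_na": self.target_corr_na,
            "target_corr_pa": self.target_corr_pa,
        }
        for name, rho in rhos.items():
            if not -1 <= rho <= 1:
                raise CohortConfigError(
                    f"{name}={rho} is not a correlation in [-1, 1]; the implied "
                    "severity/measure covariance would not be positive semidefinite"
                )
        # One-factor structure: corr matrix is [1, rho; rho^T, rho rho^T + D],
        # PSD for any |rho| <= 1; an explicit eigenvalue check guards rounding.
        r = np.array(list(rhos.values()))
        c = np.empty((4, 4))
        c[0, 0] = 1.0
        c[0, 1:] = c[1:, 0] = r
        c[1:, 1:] = np.outer(r, r)
        np.fill_diagonal(c, 1.0)
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise CohortConfigError(
                "target correlations do not form a positive-semidefinite structure"
            )

    def replace(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class CommEvent:
    """One call or text event in a participant's log."""

    timestamp: float            # seconds since the participant's start
    channel: str                # "call" | "text"
    direction: str              # "incoming" | "outgoing"
    status: str                 # "answered" | "missed" | "na"
    phone_idle: bool
    contact_id: str

    def __post_init__(self):
        if self.channel not in ("call", "text"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.direction not in ("incoming", "outgoing"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.status not in ("answered", "missed", "na"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "missed" and not (
            self.channel == "call" and self.direction == "incoming"
        ):
            raise ValueError("status='missed' only valid for incoming calls")


@dataclass
class ParticipantRecord:
    """One subject's raw streams plus baseline self-reports.

    ``accel_t`` / ``accel_mag`` hold the 1 Hz magnitude series (timestamps
    strictly increasing, nominal 1 s spacing with gaps allowed).  Missing
    self-reports are ``math.nan``.
    """

    participant_id: str
    duration_s: float
    accel_t: np.ndarray
    accel_mag: np.ndarray
    calls: list[CommEvent] = field(default_factory=list)
    texts: list[CommEvent] = field(default_factory=list)
    sias: int = 0
    dass_dep: float = math.nan
    panas_na: float = math.nan
    panas_pa: float = math.nan

    def validate(self) -> None:
        if not 0 <= self.sias <= 80:
            raise ValueError(f"SIAS {self.sias} outside [0, 80]")
        if len(self.accel_t) and np.any(np.diff(self.accel_t) <= 0):
            raise ValueError("accelerometer timestamps not strictly increasing")
        for ev in self.calls:
            if ev.channel != "call":
                raise ValueError("non-call event in calls list")
        for ev in self.texts:
            if ev.channel != "text":
                raise ValueError("non-text event in texts list")
        for ev in list(self.calls) + list(self.texts):
            if not 0 <= ev.timestamp <= self.duration_s:
                raise ValueError("event timestamp outside observation window")

    def __eq__(self, other):
        if not isinstance(other, ParticipantRecord):
            return NotImplemented
        def _nan_eq(a, b):
            return (math.isnan(a) and math.isnan(b)) or a == b
        return (
            self.participant_id == other.participant_id
            and np.array_equal(self.accel_t, other.accel_t)
            and np.array_equal(self.accel_mag, other.accel_mag)
            and self.calls == other.calls
            and self.texts == other.texts
            and self.sias == other.sias
            and _nan_eq(self.dass_dep, other.dass_dep)
            and _nan_eq(self.panas_na, other.panas_na)
            and _nan_eq(self.panas_pa, other.panas_pa)
        )


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _gen_accel(rng: np.random.Generator, cfg: CohortConfig, z: float,
               duration_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Baseline noise + movement bouts + severity-scaled gait sinusoid.

    Resting magnitude sits near gravity (9.81 m/s^2) with small jitter.
    Movement bouts arrive as an alternating renewal process; within a bout
    the magnitude oscillates at the gait period with amplitude
    max(0, a0 + amplitude_slope*z) plus extra motion noise.  The gait phase
    is coherent per participant (one walker, one stride phase), so the
    spectral line stays sharp across bouts.  One or two multi-minute
    recording gaps per day emulate app dropouts.

    With ``variance_compensation`` the in-bout noise variance is lowered by
    the oscillation's own power so the total movement energy is constant
    across severity: only the periodic structure, not the variance, carries
    the severity signal.
    """
    if cfg.accel_full_length:
        span = duration_s
    else:
        span = min(duration_s, cfg.accel_days_cap * 86400.0)
    dt = 1.0 / cfg.accel_rate
    n = int(round(span / dt))
    t = np.arange(n, dtype=float) * dt
    mag = 9.81 + rng.normal(0.0, 0.08, n)

    # Alternating rest/active renewal process; mean bout 8 min.
    mean_active = 480.0
    mean_rest = mean_active * (1.0 - cfg.active_fraction) / cfg.active_fraction
    amp = max(0.0, cfg.gait_amplitude_base + cfg.amplitude_slope * z)
    omega = 2.0 * math.pi / cfg.gait_period_s
    phase0 = rng.uniform(0.0, 2.0 * math.pi)  # coherent per participant
    if cfg.variance_compensation:
        # constant total bout variance; default target covers the largest
        # amplitude the slopes reach over |z| <= 3
        if cfg.bout_var_target is not None:
            bout_var = cfg.bout_var_target
        else:
            a_max = cfg.gait_amplitude_base + abs(cfg.amplitude_slope) * 3.0
            bout_var = a_max * a_max / 2.0 + 0.1225
        noise_sd = math.sqrt(max(bout_var - amp * amp / 2.0, 0.01))
    else:
        noise_sd = 0.35
    # per-participant movement style: AR smoothness of in-bout motion noise
    # (independent of severity) and a slow gait phase drift
    phi = cfg.gait_noise_ar
    if cfg.gait_noise_ar_jitter > 0:
        phi = float(rng.uniform(phi - cfg.gait_noise_ar_jitter,
                                phi + cfg.gait_noise_ar_jitter))
        phi = min(max(phi, 0.0), 0.99)

    def bout_noise(m: int) -> np.ndarray:
        white = rng.normal(0.0, noise_sd, m)
        if phi <= 0:
            return white
        # AR(1) with the same marginal variance as the white case
        from scipy.signal import lfilter
        innov = white * math.sqrt(1.0 - phi * phi)
        return lfilter([1.0], [1.0, -phi], innov)

    def gait_phase(tt: np.ndarray) -> np.ndarray:
        base = omega * tt + phase0
        if cfg.gait_phase_jitter <= 0:
            return base
        drift = np.cumsum(rng.normal(0.0, cfg.gait_phase_jitter, len(tt)))
        return base + drift

    pos = rng.exponential(mean_rest) if mean_rest > 0 else 0.0
    active = np.zeros(n, dtype=bool)
    while pos < span:
        bout = rng.exponential(mean_active)
        i0, i1 = int(pos / dt), min(n, int((pos + bout) / dt))
        if i1 > i0:
            active[i0:i1] = True
            tt = t[i0:i1]
            mag[i0:i1] += amp * np.sin(gait_phase(tt))
            mag[i0:i1] += bout_noise(i1 - i0)
        pos += bout + (rng.exponential(mean_rest) if mean_rest > 0 else 0.0)

    # Recording gaps: ~1.5/day, 2-10 min each.
    keep = np.ones(n, dtype=bool)
    n_gaps = rng.poisson(1.5 * span / 86400.0)
    for _ in range(n_gaps):
        g0 = rng.uniform(0.0, span)
        glen = rng.uniform(120.0, 600.0)
        keep[(t >= g0) & (t < g0 + glen)] = False
    return t[keep], mag[keep]


def _gen_comm(rng: np.random.Generator, cfg: CohortConfig, z: float,
              duration_s: float) -> tuple[list[CommEvent], list[CommEvent]]:
    """Thinned Poisson event streams per contact, severity-tilted.

    Each participant has 1+Poisson(6) contacts with Dirichlet rate shares.
    Incoming events per contact follow a homogeneous Poisson process whose
    total rate is comm_rate_base*exp(comm_rate_slope*z) per day; ~78% of
    events are texts.  Incoming texts draw a log-normal reply latency with
    log-mean shifted by reply_delay_slope*z; incoming calls are missed with
    probability sigmoid(logit(0.25) + missed_call_slope*z), and missed
    calls trigger a call-back after a similarly tilted latency.
    """
    days = duration_s / 86400.0
    total_rate = cfg.comm_rate_base * math.exp(cfg.comm_rate_slope * z)
    n_contacts = 1 + rng.poisson(6)
    shares = rng.dirichlet(np.ones(n_contacts))
    p_text = 0.78
    p_missed = _sigmoid(math.log(0.25 / 0.75) + cfg.missed_call_slope * z)
    log_delay_mu = math.log(300.0) + cfg.reply_delay_slope * z

    calls: list[CommEvent] = []
    texts: list[CommEvent] = []

    def _idle() -> bool:
        return bool(rng.random() < 0.4)

    for c in range(n_contacts):
        contact = f"c{c:03d}"
        lam = total_rate * shares[c] * days  # expected incoming events
        n_ev = rng.poisson(lam)
        for ts in np.sort(rng.uniform(0.0, duration_s, n_ev)):
            ts = float(ts)
            if rng.random() < p_text:
                texts.append(CommEvent(ts, "text", "incoming", "na", _idle(), contact))
                if rng.random() < 0.8:  # reply
                    delay = rng.lognormal(log_delay_mu, 1.0)
                    tr = ts + delay
                    if tr <= duration_s:
                        texts.append(
                            CommEvent(tr, "text", "outgoing", "na", _idle(), contact))
            else:
                missed = rng.random() < p_missed
                status = "missed" if missed else "answered"
                calls.append(CommEvent(ts, "call", "incoming", status, _idle(), contact))
                if missed and rng.random() < 0.7:  # call back
                    delay = rng.lognormal(log_delay_mu + math.log(2.0), 1.0)
                    tr = ts + delay
                    if tr <= duration_s:
                        calls.append(
                            CommEvent(tr, "call", "outgoing", "na", _idle(), contact))
        # Spontaneous outgoing events (40% of the incoming rate).
        n_out = rng.poisson(0.4 * lam)
        for ts in np.sort(rng.uniform(0.0, duration_s, n_out)):
            ts = float(ts)
            if rng.random() < p_text:
                texts.append(CommEvent(ts, "text", "outgoing", "na", _idle(), contact))
            else:
                calls.append(CommEvent(ts, "call", "outgoing", "na", _idle(), contact))

    calls.sort(key=lambda e: e.timestamp)
    texts.sort(key=lambda e: e.timestamp)
    return calls, texts


def _gen_surveys(rng: np.random.Generator, cfg: CohortConfig,
                 z: float) -> tuple[float, float, float]:
    """One-factor model: measure = rho*z + sqrt(1-rho^2)*eps, then rescaled."""
    def factor(rho: float) -> float:
        return rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal()

    dep = float(np.clip(round(7.0 + 4.0 * factor(cfg.target_corr_depression)), 0, 21))
    na = float(np.clip(round(22.0 + 7.0 * factor(cfg.target_corr_na)), 10, 50))
    pa = float(np.clip(round(30.0 + 7.0 * factor(cfg.target_corr_pa)), 10, 50))
    return dep, na, pa


def generate_cohort(config: CohortConfig) -> list[ParticipantRecord]:
    """Generate a seeded cohort of raw sensor + self-report records.

    Deterministic: equal configs (including seed) yield identical cohorts.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    # One child stream per participant plus one for missingness, so that
    # per-participant draws are independent of cohort size ordering quirks.
    children = root.spawn(config.n_participants + 1)
    records: list[ParticipantRecord] = []
    for i in range(config.n_participants):
        rng = np.random.default_rng(children[i])
        z = float(rng.normal())
        sias = int(np.clip(round(SIAS_MEAN + SIAS_SD * z), 0, 80))
        duration_s = max(2.0, rng.normal(config.duration_days_mean,
                                         config.duration_days_sd)) * 86400.0
        t, mag = _gen_accel(rng, config, z, duration_s)
        calls, texts = _gen_comm(rng, config, z, duration_s)
        dep, na, pa = _gen_surveys(rng, config, z)
        rec = ParticipantRecord(
            participant_id=f"p{i:03d}", duration_s=duration_s,
            accel_t=t, accel_mag=mag, calls=calls, texts=texts,
            sias=sias, dass_dep=dep, panas_na=na, panas_pa=pa,
        )
        rec.validate()
        records.append(rec)

    miss_rng = np.random.default_rng(children[-1])
    for rec in records:
        if miss_rng.random() < config.missing_rate_dep:
            rec.dass_dep = math.nan
        if miss_rng.random() < config.missing_rate_na:
            rec.panas_na = math.nan
        if miss_rng.random() < config.missing_rate_pa:
            rec.panas_pa = math.nan
    return records


# ---------------------------------------------------------------------------
# Plain-CSV persistence
# ---------------------------------------------------------------------------

def write_cohort(cohort: Sequence[ParticipantRecord], directory: str | Path) -> list[Path]:
    """Write ``accel.csv``, ``comm.csv`` and ``surveys.csv`` under *directory*.

    Output is byte-stable for a fixed cohort (fixed column order, repr-exact
    floats, '\\n' line endings); empty self-report cells mark MISSING.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    accel_rows = []
    for rec in cohort:
        accel_rows.append(pd.DataFrame({
            "participant_id": rec.participant_id,
            "t_seconds": rec.accel_t,
            "magnitude": rec.accel_mag,
        }))
    accel = (pd.concat(accel_rows, ignore_index=True) if accel_rows
             else pd.DataFrame(columns=["participant_id", "t_seconds", "magnitude"]))

    comm_rows = []
    for rec in cohort:
        for ev in sorted(list(rec.calls) + list(rec.texts), key=lambda e: e.timestamp):
            comm_rows.append((rec.participant_id, ev.timestamp, ev.channel,
                              ev.direction, ev.status, ev.phone_idle, ev.contact_id))
    comm = pd.DataFrame(
        comm_rows, columns=["participant_id", "t_seconds", "channel",
                            "direction", "status", "phone_idle", "contact_id"])

    surveys = pd.DataFrame({
        "participant_id": [r.participant_id for r in cohort],
        "duration_s": [r.duration_s for r in cohort],
        "sias": [r.sias for r in cohort],
        "dass_dep": [r.dass_dep for r in cohort],
        "panas_na": [r.panas_na for r in cohort],
        "panas_pa": [r.panas_pa for r in cohort],
    })

    paths = []
    for name, df in ((ACCEL_FILE, accel), (COMM_FILE, comm), (SURVEY_FILE, surveys)):
        p = directory / name
        # repr round-trips doubles exactly; pandas' default formatter does not
        df.to_csv(p, index=False, lineterminator="\n",
                  float_format=lambda v: repr(float(v)))
        paths.append(p)
    return paths


def read_cohort(directory: str | Path) -> list[ParticipantRecord]:
    """Read a cohort written by :func:`write_cohort`, validating invariants.

    Raises :class:`CohortParseError` naming the file and line on malformed
    rows, non-monotone accelerometer timestamps, or events that violate the
    CommEvent invariants (e.g. a text marked 'missed').
    """
    directory = Path(directory)
    try:
        # round_trip parsing: read(write(x)) must be bit-exact
        accel = pd.read_csv(directory / ACCEL_FILE, float_precision="round_trip")
        comm = pd.read_csv(directory / COMM_FILE, float_precision="round_trip")
        surveys = pd.read_csv(directory / SURVEY_FILE,
                              float_precision="round_trip")
    except (pd.errors.ParserError, FileNotFoundError, pd.errors.EmptyDataError) as e:
        raise CohortParseError(f"cannot read cohort in {directory}: {e}") from e

    for name, df, cols in (
        (ACCEL_FILE, accel, ["participant_id", "t_seconds", "magnitude"]),
        (COMM_FILE, comm, ["participant_id", "t_seconds", "channel", "direction",
                           "status", "phone_idle", "contact_id"]),
        (SURVEY_FILE, surveys, ["participant_id", "sias", "dass_dep",
                                "panas_na", "panas_pa"]),
    ):
        missing_cols = [c for c in cols if c not in df.columns]
        if missing_cols:
            raise CohortParseError(f"{name}: missing columns {missing_cols}")

    records: list[ParticipantRecord] = []
    accel_g = dict(list(accel.groupby("participant_id", sort=False)))
    comm_g = dict(list(comm.groupby("participant_id", sort=False)))
    for row in surveys.itertuples():
        pid = row.participant_id
        a = accel_g.get(pid)
        if a is None:
            t = np.array([]); mag = np.array([])
        else:
            t = a["t_seconds"].to_numpy(float)
            mag = a["magnitude"].to_numpy(float)
            bad = np.nonzero(np.diff(t) <= 0)[0]
            if bad.size:
                # +2: header line plus 1-based indexing of the offending row
                line = int(a.index[bad[0] + 1]) + 2
                raise CohortParseError(
                    f"{ACCEL_FILE}, line {line}: non-monotone timestamp for {pid}")
        calls: list[CommEvent] = []
        texts: list[CommEvent] = []
        c = comm_g.get(pid)
        if c is not None:
            for r in c.itertuples():
                try:
                    ev = CommEvent(float(r.t_seconds), str(r.channel),
                                   str(r.direction), str(r.status),
                                   bool(r.phone_idle), str(r.contact_id))
                except ValueError as e:
                    raise CohortParseError(
                        f"{COMM_FILE}, line {int(r.Index) + 2}: {e}") from e
                (calls if ev.channel == "call" else texts).append(ev)
        duration = float(getattr(row, "duration_s", math.nan))
        if math.isnan(duration):
            candidates = [t[-1] if len(t) else 0.0]
            candidates += [ev.timestamp for ev in calls + texts]
            duration = max(candidates)
        rec = ParticipantRecord(
            participant_id=str(pid), duration_s=duration, accel_t=t, accel_mag=mag,
            calls=calls, texts=texts, sias=int(row.sias),
            dass_dep=float(row.dass_dep), panas_na=float(row.panas_na),
            panas_pa=float(row.panas_pa),
        )
        try:
            rec.validate()
        except ValueError as e:
            raise CohortParseError(f"{SURVEY_FILE}: participant {pid}: {e}") from e
        records.append(rec)
    return records
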