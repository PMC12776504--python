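"""Synthetic resting-state cohorts with known directed coupling.

The study's raw EEG is not publicly deposited, so benchmarking and calibration
run on simulated cohorts: each subject is a stable multivariate autoregressive
(MVAR) system over the 28-region atlas, forward-projected to 64 sensors with
additive white sensor noise. Every region carries a damped AR(2) oscillation
whose resonance sits at the centre of one of the five classical EEG bands;
directed cross-couplings therefore concentrate their partial directed
coherence near the source region's resonance, giving each ground-truth edge a
band tag that band-resolved PDC can be scored against.

Cohort-level asymmetries emulate the study's qualitative findings:

* ``stroke_pre`` — reduced outflow from the affected SMA and unaffected vPM,
  increased outflow from the affected INS and affected dorsalA6, vs HC;
* ``stroke_post`` — increased outflow from the unaffected M1 and affected
  PoG, vs ``stroke_pre``.

All generator choices (dynamics, effect sizes, noise) are stand-ins for real
cortical data; see docs/methods.md for what they do and do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import RegionAtlas, default_atlas
from .containers import Recording, SourceTimeSeries

CONDITIONS = ("HC", "stroke_pre", "stroke_post")

#: band name -> resonance centre frequency (Hz) used for region oscillators
BAND_CENTERS = {
    "delta": 2.5,
    "theta": 6.0,
    "alpha": 10.5,
    "beta": 21.5,
    "gamma": 40.0,
}
BAND_ORDER = tuple(BAND_CENTERS)
#: within-band detuning (Hz) separating regions sharing a band
BAND_SPREAD = {
    "delta": 0.8,
    "theta": 1.2,
    "alpha": 1.8,
    "beta": 5.0,
    "gamma": 6.0,
}

#: feed-forward generation ranks: couplings only run from lower to higher
#: rank, so the coupling graph is acyclic and the MVAR eigenvalues remain
#: exactly the diagonal oscillator poles (stability by construction). The
#: regions whose outflow carries the cohort effects come first so they all
#: have outgoing edges.
GENERATION_RANK = (
    "SMA", "dorsalA6", "M1", "PoG", "INS", "vPM",
    "CG", "IPL", "MFG", "MTG", "Pcun", "SPL", "STG", "pSTS",
)

#: generator defaults — the simulated study conditions
DEFAULT_FS = 500.0
DEFAULT_DURATION_S = 180.0
DEFAULT_N_SENSORS = 64
DEFAULT_SNR_DB = 20.0
AR_ORDER = 5
#: per-band pole radii (roughly constant-Q resonances). Sharper poles at low
#: frequency would make the oscillator's gain so large that, once marginal
#: variances are equalized, its innovation share drops below identifiability
#: (the lagged regressors become collinear); these radii keep every region's
#: innovation at >= ~1% of its variance.
OSC_RADII = {
    "delta": 0.80,
    "theta": 0.85,
    "alpha": 0.90,
    "beta": 0.93,
    "gamma": 0.95,
}
COUPLING_STRENGTH = 4.0     # weight in units of the target's resonance |A|
MIN_INNOVATION_SHARE = 0.01  # identifiability guard in the equalizer
#: bands whose regions may RECEIVE couplings; slower resonances amplify any
#: incoming broadband drive by 1/|A(res)| (hundreds at delta), so inbound
#: edges are restricted to the faster bands while any band may send
TARGET_BANDS = ("alpha", "beta", "gamma")
EDGES_PER_REGION = 2        # outgoing edges per source region
CROSS_HEMI_PROB = 0.25      # probability an edge targets the other hemisphere
STROKE_DOWN = 0.6           # -40% on down-weighted outflows
STROKE_UP = 1.4             # +40% on up-weighted outflows
SUBJECT_JITTER_SIGMA = 0.1  # lognormal sigma of per-subject weight jitter
STABILITY_LIMIT = 0.995     # max companion spectral radius accepted


@dataclass
class CouplingGraph:
    """Ground-truth directed coupling template.

    edges: list of (source_label, target_label, band, weight); self-dynamics
    live in the AR diagonal, never in edges.
    """

    edges: list[tuple[str, str, str, float]]
    condition: str
    lesion_side: str = "none"
    region_bands: dict[str, str] = field(default_factory=dict)
    region_freqs: dict[str, float] = field(default_factory=dict)
    atlas: RegionAtlas = field(default_factory=default_atlas)

    def __post_init__(self):
        labels = set(self.atlas.labels)
        for src, tgt, band, w in self.edges:
            if src == tgt:
                raise ValueError(f"self-loop edge {src}->{tgt}")
            if src not in labels or tgt not in labels:
                raise ValueError(f"edge references unknown region {src}->{tgt}")
            if not np.isfinite(w):
                raise ValueError("non-finite coupling strength")
            if band not in BAND_CENTERS:
                raise ValueError(f"unknown band {band!r}")

    def out_strength(self, label: str) -> float:
        return float(sum(w for s, _, _, w in self.edges if s == label))

    def coefficient_tensor(self, fs: float = DEFAULT_FS) -> np.ndarray:
        """AR coefficient stack A of shape (p, R, R); A[r][i, j] couples
        region j at lag r+1 into region i."""
        R = self.atlas.n_regions
        A = np.zeros((AR_ORDER, R, R))
        idx = {lab: i for i, lab in enumerate(self.atlas.labels)}
        for lab, i in idx.items():
            f0 = self.region_freqs.get(lab,
                                       BAND_CENTERS[self.region_bands[lab]])
            rho = OSC_RADII[self.region_bands[lab]]
            w0 = 2.0 * np.pi * f0 / fs
            A[0, i, i] = 2.0 * rho * np.cos(w0)
            A[1, i, i] = -rho**2
        for src, tgt, _, w in self.edges:
            A[0, idx[tgt], idx[src]] += w
        return A

    def spectral_radius(self, fs: float = DEFAULT_FS) -> float:
        return companion_spectral_radius(self.coefficient_tensor(fs))

    def innovation_sds(self, fs: float = DEFAULT_FS, n_iter: int = 8,
                       floor: float = 1e-3) -> np.ndarray:
        """Per-region innovation SDs equalizing the stationary variances.

        The stationary variance of a near-unit-circle AR(2) resonance grows
        without bound at low frequency, which would let delta-band regions
        dwarf gamma-band ones by orders of magnitude; a fixed-point
        iteration on the companion-form discrete Lyapunov equation rescales
        every innovation so each region's marginal variance is ~1 (as in
        broadband-normalized EEG). Regions whose inherited variance already
        exceeds the target keep a floor innovation.
        """
        from scipy import linalg as sla

        A = self.coefficient_tensor(fs)
        p, R, _ = A.shape
        F = np.zeros((R * p, R * p))
        F[:R, :] = np.concatenate(list(A), axis=1)
        if p > 1:
            F[R:, :-R] = np.eye(R * (p - 1))
        sds = np.empty(R)
        for i, lab in enumerate(self.atlas.labels):
            f0 = self.region_freqs.get(lab,
                                       BAND_CENTERS[self.region_bands[lab]])
            rho = OSC_RADII[self.region_bands[lab]]
            w0 = 2.0 * np.pi * f0 / fs
            a1 = 2.0 * rho * np.cos(w0)
            a2 = -rho**2
            var = (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1**2))
            sds[i] = 1.0 / np.sqrt(var)   # oscillator-only initial guess
        v = np.ones(R)
        for _ in range(n_iter):
            Q = np.zeros((R * p, R * p))
            Q[:R, :R] = np.diag(sds**2)
            S = sla.solve_discrete_lyapunov(F, Q, method="bilinear")
            v = np.maximum(np.diag(S)[:R], 1e-12)
            sds = np.maximum(sds / np.sqrt(v), floor)
        # identifiability guard: every region keeps a minimum innovation
        # share of its marginal variance, else its lagged values are a
        # near-deterministic combination of the other regressors and the
        # pooled regression loses identifiability
        sds = np.maximum(sds, np.sqrt(MIN_INNOVATION_SHARE * v))
        return sds

    def scaled_edges(self, factors: dict[str, float]) -> "CouplingGraph":
        """New graph with outgoing weights of selected source regions scaled."""
        edges = [
            (s, t, b, w * factors.get(s, 1.0)) for s, t, b, w in self.edges
        ]
        return CouplingGraph(edges, self.condition, self.lesion_side,
                             dict(self.region_bands),
                             dict(self.region_freqs), self.atlas)


@dataclass
class LeadField:
    """Sensor gain matrix (sensors x sources), unit-normalized columns."""

    gain: np.ndarray
    sensor_labels: list[str]
    source_labels: list[str]

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        ns, nr = self.gain.shape
        if len(self.sensor_labels) != ns or len(self.source_labels) != nr:
            raise ValueError("label counts disagree with gain shape")
        if np.linalg.matrix_rank(self.gain) < nr:
            raise ValueError("leadfield is column rank deficient")


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the companion matrix of an MVAR coefficient stack."""
    p, R, _ = A.shape
    comp = np.zeros((R * p, R * p))
    comp[:R, :] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[R:, :-R] = np.eye(R * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def _region_dynamics(atlas: RegionAtlas):
    """Assign each homotopic pair a band and a detuned resonance frequency.

    Bands cycle over the base regions; regions sharing a band are detuned
    within it so no two base regions have identical poles. Homotopes share
    band and frequency (mirror symmetry).
    """
    bands: dict[str, str] = {}
    freqs: dict[str, float] = {}
    for k, base in enumerate(atlas.base_names):
        b = BAND_ORDER[k % len(BAND_ORDER)]
        occurrence = k // len(BAND_ORDER)
        f0 = BAND_CENTERS[b] + (occurrence - 1) * BAND_SPREAD[b]
        for h in ("L", "R"):
            bands[f"{base}-{h}"] = b
            freqs[f"{base}-{h}"] = f0
    return bands, freqs


def _mirror(label: str, atlas: RegionAtlas) -> str:
    return atlas.homotope(label)


def _diag_transfer_mag(f_osc: float, f_eval: float, rho: float,
                       fs: float = DEFAULT_FS) -> float:
    """|1 - a1 e^{-iw} - a2 e^{-2iw}|: magnitude of an AR(2) oscillator's
    characteristic polynomial at another frequency (the reciprocal of its
    gain there)."""
    w0 = 2.0 * np.pi * f_osc / fs
    w = 2.0 * np.pi * f_eval / fs
    a1 = 2.0 * rho * np.cos(w0)
    a2 = -rho**2
    z = np.exp(-1j * w)
    return float(abs(1.0 - a1 * z - a2 * z * z))


def build_cohort_template(
    condition: str,
    lesion_side: str = "none",
    seed: int = 0,
    atlas: RegionAtlas | None = None,
) -> CouplingGraph:
    """Construct the condition-level coupling template.

    The HC template is exactly hemisphere-symmetric by construction: edges are
    drawn among left-hemisphere regions (plus a few homotopic links) and
    mirrored with identical weights. Stroke templates multiply the outgoing
    weights of the targeted regions by fixed factors (x0.6 / x1.4) relative to
    the HC base built from the same seed.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition == "HC":
        if lesion_side not in ("none", ""):
            raise ValueError("HC subjects have no lesion side")
        lesion_side = "none"
    elif lesion_side not in ("left", "right"):
        raise ValueError("stroke conditions require lesion_side left|right")

    atlas = atlas or default_atlas()
    rng = np.random.default_rng(seed)
    bands, freqs = _region_dynamics(atlas)
    rank = {base: r for r, base in enumerate(GENERATION_RANK)}
    for base in atlas.base_names:
        if base not in rank:  # custom atlases: fall back to label order
            rank[base] = len(rank)

    edges: list[tuple[str, str, str, float]] = []
    # feed-forward topology: every source couples into strictly higher-rank
    # bases of a different band (possibly crossing hemispheres); drawn for
    # the left hemisphere and mirrored exactly, so the HC template is
    # hemisphere-symmetric and the coupling graph is acyclic (stability by
    # construction). Each weight is scaled to the target's own transfer
    # magnitude at the source's resonance so per-hop variance amplification
    # stays bounded (~COUPLING_GAIN^2) along cascades.
    for base in atlas.base_names:
        src = f"{base}-L"
        downstream = [b for b in atlas.base_names
                      if rank[b] > rank[base]
                      and bands[f"{b}-L"] != bands[src]
                      and bands[f"{b}-L"] in TARGET_BANDS]
        if not downstream:
            continue
        n_out = min(EDGES_PER_REGION, len(downstream))
        targets = rng.choice(downstream, size=n_out, replace=False)
        for tgt_base in targets:
            cross = rng.random() < CROSS_HEMI_PROB
            tgt = f"{tgt_base}-{'R' if cross else 'L'}"
            res_mag = _diag_transfer_mag(freqs[tgt], freqs[tgt],
                                         OSC_RADII[bands[tgt]])
            w = COUPLING_STRENGTH * res_mag * rng.uniform(0.8, 1.2)
            edges.append((src, tgt, bands[src], w))
            edges.append((_mirror(src, atlas), _mirror(tgt, atlas),
                          bands[src], w))

    graph = CouplingGraph(edges, condition, lesion_side, bands, freqs, atlas)

    if condition != "HC":
        aff = "L" if lesion_side == "left" else "R"
        una = "R" if lesion_side == "left" else "L"
        factors = {
            f"SMA-{aff}": STROKE_DOWN,
            f"vPM-{una}": STROKE_DOWN,
            f"INS-{aff}": STROKE_UP,
            f"dorsalA6-{aff}": STROKE_UP,
        }
        graph = graph.scaled_edges(factors)
        if condition == "stroke_post":
            graph = graph.scaled_edges(
                {f"M1-{una}": STROKE_UP, f"PoG-{aff}": STROKE_UP}
            )

    # enforce stability, uniformly shrinking cross-couplings if ever needed
    for _ in range(50):
        if graph.spectral_radius() < STABILITY_LIMIT:
            break
        graph = graph.scaled_edges({lab: 0.9 for lab in atlas.labels})
    else:  # pragma: no cover - generator defaults are stable
        raise RuntimeError("could not stabilize coupling template")
    return graph


def simulate_mvar(
    template: CouplingGraph | np.ndarray,
    atlas: RegionAtlas | None = None,
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    burn_in: int = 2000,
) -> SourceTimeSeries:
    """Simulate region time courses from a stable MVAR system.

    Innovations are unit-variance Gaussian; the first ``burn_in`` samples are
    discarded so the output is (approximately) stationary. Identical seeds
    give bit-identical output.
    """
    atlas = atlas or default_atlas()
    innovation_sd = None
    if isinstance(template, CouplingGraph):
        A = template.coefficient_tensor(fs)
        innovation_sd = template.innovation_sds(fs)
    else:
        A = np.asarray(template, dtype=float)
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    p, R, _ = A.shape
    if companion_spectral_radius(A) >= 1.0:
        raise ValueError("MVAR template is unstable (spectral radius >= 1)")
    n = int(round(duration_s * fs))
    if n < 10 * p * R:  # >= 10 samples per AR parameter per region equation
        raise ValueError("duration too short for the AR order")

    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n + burn_in, R))
    if innovation_sd is not None:
        eps *= innovation_sd
    A_stacked = np.concatenate(list(A), axis=1)  # R x (R*p), lag-major
    buf = np.zeros(R * p)
    out = np.empty((n + burn_in, R))
    for t in range(n + burn_in):
        x = A_stacked @ buf + eps[t]
        buf[R:] = buf[:-R]
        buf[:R] = x
        out[t] = x
    labels = list(atlas.labels) if R == atlas.n_regions else [
        f"r{i}" for i in range(R)
    ]
    return SourceTimeSeries(out[burn_in:].T.copy(), fs, labels)


def make_leadfield(
    n_sensors: int,
    atlas: RegionAtlas | None = None,
    seed: int = 0,
    coherence: float = 0.0,
) -> LeadField:
    """Random full-rank forward model with unit-normalized source columns.

    A geometric surrogate with no head-model physics: topographies are a
    random orthonormal frame in sensor space (well-separated sources), each
    optionally blended with a random Gaussian direction to introduce mutual
    coherence (``coherence`` in [0, 1]; 0 keeps the frame orthonormal).
    """
    atlas = atlas or default_atlas()
    n_sources = atlas.n_regions
    if n_sensors < n_sources:
        raise ValueError("need at least as many sensors as sources")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_sensors, n_sources))
    ortho, _ = np.linalg.qr(raw)
    gain = (1.0 - coherence) * ortho + coherence * raw / np.linalg.norm(
        raw, axis=0, keepdims=True)
    gain /= np.linalg.norm(gain, axis=0, keepdims=True)
    sensors = [f"E{i + 1:03d}" for i in range(n_sensors)]
    return LeadField(gain, sensors, list(atlas.labels))


def project_to_sensors(
    sources: SourceTimeSeries,
    leadfield: LeadField,
    snr_db: float = DEFAULT_SNR_DB,
    seed: int = 0,
    **metadata,
) -> Recording:
    """Forward-project sources and add spatially white sensor noise.

    Noise variance is set so that total signal power / noise power matches
    ``snr_db``; ``snr_db = inf`` disables noise.
    """
    if sources.data.shape[0] != leadfield.gain.shape[1]:
        raise ValueError("source count disagrees with leadfield columns")
    clean = leadfield.gain @ sources.data
    if np.isinf(snr_db):
        data = clean
    else:
        if not np.isfinite(snr_db):
            raise ValueError("snr_db must be finite or +inf")
        rng = np.random.default_rng(seed)
        p_sig = float(np.mean(clean**2))
        p_noise = p_sig / 10.0 ** (snr_db / 10.0) if p_sig > 0 else 1.0
        data = clean + rng.standard_normal(clean.shape) * np.sqrt(p_noise)
    return Recording(
        data=data,
        fs=sources.fs,
        channel_labels=list(leadfield.sensor_labels),
        subject_id=metadata.get("subject_id", sources.subject_id),
        group=metadata.get("group", sources.group),
        session=metadata.get("session", sources.session),
        lesion_side=metadata.get("lesion_side", sources.lesion_side),
    )


def generate_cohort(
    n_per_group: int,
    conditions: tuple[str, ...] = CONDITIONS,
    seed: int = 0,
    atlas: RegionAtlas | None = None,
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
    n_sensors: int = DEFAULT_N_SENSORS,
    snr_db: float = DEFAULT_SNR_DB,
) -> tuple[list[Recording], dict[tuple[str, str], CouplingGraph], LeadField]:
    """Generate a seeded cohort of recordings with ground-truth graphs.

    Stroke subjects appearing in both ``stroke_pre`` and ``stroke_post``
    share a subject_id (paired sessions) and per-subject coupling jitter, so
    pre/post differences reflect only the condition template change. Lesion
    sides alternate left/right (an 11/11 split at the default n=22).

    Returns (recordings, truth, leadfield) where truth maps
    (subject_id, session) -> the subject's jittered CouplingGraph.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if not conditions:
        raise ValueError("empty condition list")
    for c in conditions:
        if c not in CONDITIONS:
            raise ValueError(f"unknown condition {c!r}")

    atlas = atlas or default_atlas()
    root = np.random.default_rng(seed)
    template_seed = int(root.integers(2**31))
    lf = make_leadfield(n_sensors, atlas, seed=int(root.integers(2**31)))

    recordings: list[Recording] = []
    truth: dict[tuple[str, str], CouplingGraph] = {}

    def subject_graph(condition, lesion_side, jitter_rng):
        g = build_cohort_template(condition, lesion_side, template_seed, atlas)
        jitter = {
            lab: float(jitter_rng.lognormal(0.0, SUBJECT_JITTER_SIGMA))
            for lab in atlas.labels
        }
        g = g.scaled_edges(jitter)
        for _ in range(50):
            if g.spectral_radius() < STABILITY_LIMIT:
                return g
            g = g.scaled_edges({lab: 0.9 for lab in atlas.labels})
        raise RuntimeError("unstable subject graph")  # pragma: no cover

    stroke_conditions = [c for c in conditions if c != "HC"]
    if "HC" in conditions:
        for k in range(n_per_group):
            srng = np.random.default_rng((seed, 0, k))
            g = subject_graph("HC", "none", srng)
            sid = f"HC{k + 1:03d}"
            src = simulate_mvar(g, atlas, duration_s, fs,
                                seed=int(srng.integers(2**31)))
            rec = project_to_sensors(
                src, lf, snr_db, seed=int(srng.integers(2**31)),
                subject_id=sid, group="HC", session="", lesion_side="none",
            )
            recordings.append(rec)
            truth[(sid, "")] = g

    if stroke_conditions:
        for k in range(n_per_group):
            side = "left" if k < (n_per_group + 1) // 2 else "right"
            sid = f"ST{k + 1:03d}"
            for cond in stroke_conditions:
                session = "pre" if cond == "stroke_pre" else "post"
                jrng = np.random.default_rng((seed, 1, k))
                g = subject_graph(cond, side, jrng)
                src = simulate_mvar(
                    g, atlas, duration_s, fs,
                    seed=int(np.random.default_rng((seed, 2, k,
                                                    stroke_conditions.index(cond))
                                                   ).integers(2**31)),
                )
                rec = project_to_sensors(
                    src, lf, snr_db,
                    seed=int(np.random.default_rng((seed, 3, k,
                                                    stroke_conditions.index(cond))
                                                   ).integers(2**31)),
                    subject_id=sid, group="stroke", session=session,
                    lesion_side=side,
                )
                recordings.append(rec)
                truth[(sid, session)] = g
    return recordings, truth, lf
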