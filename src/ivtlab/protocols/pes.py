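"""Programmed electrical stimulation (S1-S2-S3) and reentry detection.

The inducibility test mirrors the clinical protocol: a drive train of six
S1 stimuli at a 600 ms cycle length, then a premature S2 coupled at
400 ms, decrementing in 10 ms steps until ventricular tachycardia (VT) is
induced or the pacing site stops capturing; if S2 alone fails, the scan
is repeated with an added S3 coupled at the same interval as S2.  The S1
drive is simulated once per model and checkpointed; every coupling
interval restarts from that state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..solver.monodomain import (
    ModelVersion,
    StimulusDef,
    TissueModel,
    TissueState,
    run_simulation,
)


@dataclass
class PESProtocol:
    """Parameters of the S1-S2(-S3) stimulation protocol."""

    s1_count: int = 6
    s1_bcl: float = 600.0
    s2_initial_ci: float = 400.0
    ci_decrement: float = 10.0
    ci_floor: float = 150.0  # safeguard; capture failure normally ends the scan
    enable_s3: bool = True
    stim_duration: float = 2.0
    stim_amplitude: float = -80.0
    observe_ms: float = 2500.0  # post-stimulus observation for reentry
    site_radius: float = 1.0
    min_cycles: int = 3  # unsupported reactivations for "sustained"

    def __post_init__(self):
        if self.ci_decrement <= 0:
            raise ValueError("CI decrement must be positive (the scan must terminate)")
        if self.s2_initial_ci <= 0 or self.s1_bcl <= 0:
            raise ValueError("intervals must be positive")

    @property
    def last_s1(self) -> float:
        return (self.s1_count - 1) * self.s1_bcl

    def ci_sequence(self):
        ci = self.s2_initial_ci
        while ci >= self.ci_floor:
            yield ci
            ci -= self.ci_decrement


def expand_pes(protocol: PESProtocol, ci: float, with_s3: bool = False) -> np.ndarray:
    """Stimulus onset times for one CI: S1 train, S2 at last-S1 + CI, S3 at + 2 CI."""
    if ci <= 0:
        raise ValueError("coupling interval must be positive")
    times = [k * protocol.s1_bcl for k in range(protocol.s1_count)]
    times.append(protocol.last_s1 + ci)
    if with_s3:
        times.append(protocol.last_s1 + 2 * ci)
    return np.asarray(times)


@dataclass
class InducibilityResult:
    """Outcome of one PES inducibility test."""

    outcome: str  # "VT" | "no_VT"
    stage: str  # "S2" | "S3" | "none"
    ci: float | None = None
    vt_bcl: float | None = None
    block_type: str = "none"  # none | unidirectional | bidirectional
    event_log: list = field(default_factory=list)

    @property
    def vt_rate(self) -> int | None:
        """VT rate in beats per minute."""
        return None if not self.vt_bcl else int(round(60000.0 / self.vt_bcl))

    def cell(self) -> str:
        """Compact table-cell rendering of the result."""
        if self.outcome != "VT":
            return "no VT"
        return f"{self.stage}-{self.ci:.0f} ms {self.vt_bcl:.0f} ms-{self.vt_rate} bpm"


def detect_reentry(activations: np.ndarray, last_stim_end: float, min_cycles: int = 3):
    """Sustained-reentry test on one node's activation train.

    Sustained iff at least ``min_cycles`` activations occur after the last
    stimulus has ended (no stimulus support); the VT cycle length is the
    mean inter-activation interval over the detected cycles.
    """
    acts = np.asarray(activations, dtype=float)
    acts = acts[acts > last_stim_end]
    if acts.size < min_cycles:
        return False, None
    intervals = np.diff(acts)
    return True, float(np.mean(intervals)) if intervals.size else None


def _first_after(acts: dict, node: int, t_after: float) -> float:
    t = np.asarray(acts.get(node, ()), dtype=float)
    t = t[t > t_after]
    return float(t[0]) if t.size else np.inf


def _classify_block(acts: dict, t_after: float, refs: dict) -> str:
    """Classify conduction at the channel after the premature stimulus.

    Uses the channel-interior landmarks: if the channel mid-point first
    activates from the upper end (upper before mid), entry from below
    failed while entry from above succeeded — unidirectional block at the
    lower mouth.  A shallow penetration at the very bottom of the channel
    does not count as successful entry.  If the channel interior never
    activates the block is bidirectional.
    """
    t_mid = _first_after(acts, refs["channel_mid"], t_after)
    t_hi = _first_after(acts, refs["channel_high"], t_after)
    if not np.isfinite(t_mid) and not np.isfinite(t_hi):
        return "bidirectional"
    if t_hi < t_mid:
        return "unidirectional"
    return "none"


def _conducted_through(acts: dict, t_after: float, refs: dict) -> bool:
    """True when the premature wave crossed the channel bottom-up.

    Antegrade transit (low, then mid, then high) means the wave passed the
    channel and annihilated against the outer wave: no reentrant pathway
    remains for this coupling interval, so the attempt can be closed early.
    """
    t_lo = _first_after(acts, refs["channel_low"], t_after)
    t_mid = _first_after(acts, refs["channel_mid"], t_after)
    t_hi = _first_after(acts, refs["channel_high"], t_after)
    return np.isfinite(t_hi) and t_lo <= t_mid <= t_hi


def run_inducibility_test(
    model: TissueModel,
    site_point,
    protocol: PESProtocol | None = None,
    initial: TissueState | None = None,
    reference_point=None,
    landmarks: dict | None = None,
    s1_state: TissueState | None = None,
    event_log: list | None = None,
) -> InducibilityResult:
    """Full PES inducibility test from one pacing site.

    ``landmarks`` may provide ``channel_low``/``channel_high`` points (the
    interior ends of a slow conducting channel) for block classification
    and ``probe_top`` as the default reference probe.  ``s1_state`` allows
    reusing a previously computed post-drive-train state.
    """
    protocol = protocol or PESProtocol()
    log = event_log if event_log is not None else []
    landmarks = landmarks or {}

    site_nodes = model.nodes_near(site_point, protocol.site_radius)
    site_node = model.nodes_near(site_point, 0.0)[0]
    if reference_point is None:
        reference_point = landmarks.get("probe_top", site_point)
    ref_node = model.nodes_near(reference_point, 0.0)[0]

    mouth_refs = {}
    for name in ("channel_low", "channel_mid", "channel_high"):
        if name in landmarks:
            mouth_refs[name] = int(model.nodes_near(landmarks[name], 0.0)[0])
    all_refs = sorted({int(ref_node), *mouth_refs.values()})

    # ---- S1 drive train (simulated once, checkpointed) ----
    if s1_state is None:
        s1 = StimulusDef(
            nodes=site_nodes,
            onset=0.0,
            duration=protocol.stim_duration,
            amplitude=protocol.stim_amplitude,
            period=protocol.s1_bcl,
            count=protocol.s1_count,
        )
        res1 = run_simulation(
            model,
            [s1],
            duration=protocol.last_s1 + protocol.stim_duration + 2.0,
            initial=initial,
            probes={"site": site_node},
            event_log=log,
        )
        if res1.probe_traces["site"].max() < 0.0:
            log.append((0.0, "S1 drive train failed to capture the pacing site"))
            return InducibilityResult(outcome="no_VT", stage="none", event_log=log)
        s1_state = res1.final_state
        log.append((s1_state.t, f"S1 drive complete ({protocol.s1_count} beats)"))

    stages = ["S2"] + (["S3"] if protocol.enable_s3 else [])
    for stage in stages:
        with_s3 = stage == "S3"
        for ci in protocol.ci_sequence():
            verdict, vt_bcl, block = _run_attempt(
                model, protocol, s1_state, site_nodes, site_node,
                int(ref_node), mouth_refs, all_refs, ci, with_s3, log, stage,
            )
            if verdict == "no_capture":
                log.append((0.0, f"{stage} CI {ci:.0f} ms: propagation block at pacing site"))
                break
            if verdict == "vt":
                return InducibilityResult(outcome="VT", stage=stage, ci=ci,
                                          vt_bcl=vt_bcl, block_type=block, event_log=log)
    return InducibilityResult(outcome="no_VT", stage="none", event_log=log)


def _run_attempt(model, protocol, s1_state, site_nodes, site_node, ref_node,
                 mouth_refs, all_refs, ci, with_s3, log, stage,
                 chunk_ms: float = 150.0):
    """One coupling-interval attempt, advanced in chunks with early verdicts.

    Verdicts: "no_capture" (pacing site refractory — ends the CI scan),
    "vt" (sustained reentry detected), "no_vt" (wave conducted through the
    channel antegradely, extinguished, or the observation window closed).
    """
    t2 = protocol.last_s1 + ci
    stims = [StimulusDef(nodes=site_nodes, onset=t2,
                         duration=protocol.stim_duration,
                         amplitude=protocol.stim_amplitude)]
    t_last = t2
    if with_s3:
        t_last = protocol.last_s1 + 2 * ci
        stims.append(StimulusDef(nodes=site_nodes, onset=t_last,
                                 duration=protocol.stim_duration,
                                 amplitude=protocol.stim_amplitude))
    end = t_last + protocol.stim_duration
    t_limit = end + protocol.observe_ms

    state = s1_state.copy()
    acts = {r: [] for r in all_refs}
    site_t, site_v = [], []
    captured = None
    block_logged = False
    have_channel = {"channel_low", "channel_mid", "channel_high"} <= set(mouth_refs)
    while state.t < t_limit - 1e-9:
        dur = min(chunk_ms, t_limit - state.t)
        chunk_start = state.t
        res = run_simulation(
            model, stims, dur, initial=state,
            probes={"site": site_node}, reference_nodes=all_refs,
            early_stop_quiescent=True, event_log=log,
        )
        state = res.final_state
        for r in all_refs:
            acts[r].extend(res.ref_activations[r].tolist())
        site_t.append(res.probe_times)
        site_v.append(res.probe_traces["site"])

        if captured is None and state.t >= t_last + 10.0:
            tt = np.concatenate(site_t)
            vv = np.concatenate(site_v)
            win = (tt >= t_last) & (tt <= t_last + 10.0)
            captured = bool(win.any() and vv[win].max() > 0.0)
            if not captured:
                return "no_capture", None, "none"

        if have_channel and not block_logged:
            blk = _classify_block(acts, t2 - 1.0, mouth_refs)
            if blk == "unidirectional":
                log.append((state.t, f"{stage} CI {ci:.0f} ms: unidirectional "
                                     "block at the lower channel mouth"))
                block_logged = True

        sustained, vt_bcl = detect_reentry(
            np.asarray(acts[ref_node]), end, protocol.min_cycles)
        if sustained:
            block = _classify_block(acts, t2 - 1.0, mouth_refs) if have_channel else "none"
            log.append((state.t, f"{stage} CI {ci:.0f} ms: sustained reentry, "
                                 f"VT BCL {vt_bcl:.0f} ms, block {block}"))
            return "vt", vt_bcl, block

        if have_channel and _conducted_through(acts, t_last - 1.0, mouth_refs):
            log.append((state.t, f"{stage} CI {ci:.0f} ms: antegrade conduction "
                                 "through the channel, no reentry"))
            return "no_vt", None, "none"

        if state.t < chunk_start + dur - 1e-6:
            # the run stopped early: tissue quiescent, activity extinguished
            if have_channel:
                block = _classify_block(acts, t2 - 1.0, mouth_refs)
                if block != "none":
                    log.append((state.t, f"{stage} CI {ci:.0f} ms: {block} block at "
                                         "channel, activity extinguished"))
            return "no_vt", None, "none"
    return "no_vt", None, "none"


def inducibility_matrix(
    build_model,
    versions: list[ModelVersion],
    sites,
    protocol: PESProtocol | None = None,
) -> dict:
    """Inducibility results for every (model version, pacing site) pair.

    ``build_model`` maps a ModelVersion to ``(model, landmarks,
    initial_state)`` — a ready TissueModel with any stabilization
    applied.  ``sites`` names landmarks to pace from.  Returns
    ``{version_name: {site_name: InducibilityResult}}``; each result
    carries its own event log.
    """
    protocol = protocol or PESProtocol()
    out = {}
    for version in versions:
        model, landmarks, initial = build_model(version)
        row = {}
        for site_name in sites:
            log = []
            row[site_name] = run_inducibility_test(
                model, landmarks[site_name], protocol, initial=initial,
                landmarks=landmarks, event_log=log,
            )
        out[version.name] = row
    return out
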