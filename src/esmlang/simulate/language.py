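"""Rendering of language streams coupled to the latent emotional state.

Every observed feature f carries a latent standardized value

    x_f = sum_e lambda_{f,e} * z_e + sqrt(1 - sum lambda^2) * noise,

where z is the participant's standardized emotion state at that beep and
lambda the planted loading matrix.  The three renderers then turn x into
observable data:

* transcripts -- token counts per lexicon category follow a multinomial
  whose category weights are log-linear in x; because multinomial sampling
  attenuates the correlation between the *extracted* percentage and the
  emotion, the loading vector of each content feature is pre-amplified by
  the delta-method attenuation factor so that the planted loading is the
  target correlation on the extracted scale;
* waveforms -- harmonic pulse trains with an F0 contour (slow modulation +
  declination), an amplitude envelope, per-period jitter/shimmer
  perturbations and additive noise setting the harmonics-to-noise ratio;
* keystroke logs -- entries with character/backspace events whose rates,
  speeds and press durations are log-linear in x.

Ground-truth feature values (the noiseless parameter contours summarized
with the same statistics the extractor uses, or the planted parameter
itself) are returned alongside for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ..acoustics import ACOUSTIC_FEATURES, AudioClip, hz_to_semitone, _monotone_run_slopes, _SEMITONE_TOL
from ..keyboard import TYPING_FEATURES
from ..lexicon import WORD_CATEGORIES, Lexicon, extract_content_features, load_demo_lexicon
from .config import EMOTIONS, ConfigurationError, SimulationConfig

__all__ = [
    "RenderedVoice",
    "draw_feature_latents",
    "render_transcript",
    "render_waveform",
    "render_keyboard_bin",
]

#: Words guaranteed to match no lexicon category (the unrecognized share).
FILLER_WORDS = (
    "vandaag", "morgen", "gisteren", "school", "thuis", "eten", "koffie",
    "fiets", "regen", "zon", "muziek", "boek", "film", "les", "trein",
    "stad", "winkel", "familie", "weekend", "avond", "ochtend", "middag",
    "slapen", "lopen", "praten", "kijken", "spelen", "studeren", "toets",
    "examen", "taak", "vergadering", "pauze", "weer", "buiten", "binnen",
    "samen", "daarna", "straks", "gewoon", "misschien", "dan", "toen",
    "nog", "al", "ook", "maar", "want", "omdat", "met", "voor", "na",
    "over", "onder", "tussen", "deze", "dat", "het", "de", "een", "en",
    "of", "er", "hier", "daar", "nu", "toch", "heel", "veel", "weinig",
    "beetje", "uur", "dag", "week", "tijd", "mensen", "ding", "dingen",
    "ben", "was", "heb", "had", "doen", "gaan", "komen", "zien", "maken",
)


@lru_cache(maxsize=4)
def _surfaces(lexicon: Lexicon) -> dict[str, tuple[str, ...]]:
    """Per category, surface words that match that category and no other.

    Generating only unambiguous surfaces keeps the rendered category counts
    exactly equal to the planted multinomial draws when re-extracted.
    """
    matchers = lexicon.matchers()

    def hits(tok: str) -> set[str]:
        out = set()
        for name, (exact, stems) in matchers.items():
            if tok in exact or any(tok.startswith(s) for s in stems):
                out.add(name)
        return out

    table: dict[str, tuple[str, ...]] = {}
    for name, entries in lexicon.categories.items():
        cands = []
        for e in sorted(entries):
            cands.append(e[:-1] if e.endswith("*") else e)
        uniq = tuple(t for t in cands if hits(t) == {name})
        if not uniq:
            raise ConfigurationError(f"category {name!r} has no unambiguous surface form")
        table[name] = uniq
    for w in FILLER_WORDS:
        if hits(w):
            raise ConfigurationError(f"filler word {w!r} matches category {hits(w)}")
    return table


def _content_attenuation(config: SimulationConfig, stream: str) -> dict[str, float]:
    """Delta-method shrinkage of corr(extracted %, z) per content feature.

    For a category with baseline proportion p and log-odds gain g observed
    in texts of ~N tokens, the extracted percentage carries multinomial
    noise with variance p(1-p)/N while the planted signal has SD ~ p*g, so
    the realized correlation is shrunk by s/sqrt(s^2+v).  Loadings are
    divided by this factor at rendering time.
    """
    if stream == "speech":
        base = config.speech_category_baseline
        nbar = config.speech_word_count_mean
    else:
        base = config.writing_category_baseline
        nbar = config.words_per_entry_mean * (1.0 + config.entries_per_bin_mean)
    g = config.content_logodds_gain
    out = {}
    # category rate p0*exp(g x) is lognormal in x ~ N(0,1):
    #   corr(p, x) = g*m / sd(p),  m = p0*exp(g^2/2),  var(p) = m^2*(e^{g^2}-1);
    # binomial counting over ~N tokens adds variance m(1-m)/N
    for cat in WORD_CATEGORIES:
        m = base[cat] * np.exp(g * g / 2.0)
        var_p = m * m * (np.exp(g * g) - 1.0)
        v = m * (1.0 - m) / nbar
        out[cat] = float(g * m / np.sqrt(var_p + v))
    # word count: N ~ Poisson(nbar * exp(a x))
    a = 0.3
    M = nbar * np.exp(a * a / 2.0)
    out["wc"] = float(a * M / np.sqrt(M + M * M * (np.exp(a * a) - 1.0)))
    c = config.exclam_rate
    if c > 0:
        a = 0.5
        M = c * np.exp(a * a / 2.0)
        out["exclam"] = float(a * M / np.sqrt(M + M * M * (np.exp(a * a) - 1.0)))
    else:
        out["exclam"] = 1.0
    return out


def draw_feature_latents(config: SimulationConfig, z: np.ndarray,
                         features: list[str], rng: np.random.Generator,
                         attenuation: dict[str, float] | None = None
                         ) -> dict[str, float]:
    """Latent standardized values x_f for one beep.

    ``z`` is the 7-vector of standardized emotion states.  ``attenuation``
    maps base feature names to shrinkage factors; the loading vector is
    divided by the factor (capped so squared loadings sum to <= 0.9).
    """
    out = {}
    for feat in features:
        lam = config.loadings_for(feat)
        if attenuation:
            base = feat.split(".", 1)[1]
            f = attenuation.get(base, 1.0)
            lam = lam / max(f, 1e-6)
            ss = float(lam @ lam)
            if ss > 0.9:
                lam = lam * np.sqrt(0.9 / ss)
        ss = float(lam @ lam)
        noise_sd = np.sqrt(max(1.0 - ss, 0.0))
        out[feat] = float(lam @ z + noise_sd * rng.standard_normal())
    return out


def _compose_tokens(counts: dict[str, int], n_filler: int,
                    surfaces: dict[str, tuple[str, ...]],
                    rng: np.random.Generator) -> list[str]:
    toks: list[str] = []
    for cat, k in counts.items():
        if k > 0:
            toks.extend(rng.choice(surfaces[cat], size=k))
    toks.extend(rng.choice(FILLER_WORDS, size=n_filler))
    rng.shuffle(toks)
    return toks


def render_transcript(config: SimulationConfig, x: dict[str, float],
                      stream: str, rng: np.random.Generator,
                      lexicon: Lexicon | None = None,
                      n_words: int | None = None) -> tuple[str, dict[str, int]]:
    """One transcript (or message) with category counts multinomial in x.

    ``x`` maps base feature names (wc, posemo, ...) to latent values.
    Returns the text and the realized per-category counts (plus ``wc``).
    """
    lexicon = lexicon or load_demo_lexicon()
    surfaces = _surfaces(lexicon)
    base = (config.speech_category_baseline if stream == "speech"
            else config.writing_category_baseline)
    g = config.content_logodds_gain
    if n_words is None:
        nbar = (config.speech_word_count_mean if stream == "speech"
                else config.words_per_entry_mean)
        n_words = max(2, int(rng.poisson(nbar * np.exp(0.3 * x.get("wc", 0.0)))))
    w = np.array([base[c] * np.exp(g * x.get(c, 0.0)) for c in WORD_CATEGORIES])
    w_fill = max(1.0 - sum(base.values()), 0.3)
    probs = np.append(w, w_fill)
    probs = probs / probs.sum()
    draw = rng.multinomial(n_words, probs)
    counts = dict(zip(WORD_CATEGORIES, (int(v) for v in draw[:-1])))
    toks = _compose_tokens(counts, int(draw[-1]), surfaces, rng)
    text = " ".join(toks)
    if stream == "writing":
        n_ex = int(rng.poisson(config.exclam_rate * np.exp(0.5 * x.get("exclam", 0.0))))
        text = text + "!" * n_ex
        counts["exclam"] = n_ex
    counts["wc"] = n_words
    return text, counts


@dataclass(frozen=True)
class RenderedVoice:
    """A synthesized clip plus its ground-truth acoustic parameters."""

    clip: AudioClip
    truth: dict[str, float] = field(default_factory=dict)


def render_waveform(config: SimulationConfig, x: dict[str, float],
                    base_f0_hz: float, rng: np.random.Generator) -> RenderedVoice:
    """Synthesize one voice clip with acoustic parameters log-linear in x.

    The clip alternates voiced harmonic-pulse segments and silent pauses.
    Within a segment the F0 contour is a slow sinusoidal modulation plus a
    downward declination; the amplitude envelope rises, holds and falls.
    Jitter and shimmer perturb individual pitch periods; white noise over
    the voiced samples sets the harmonics-to-noise ratio.

    The returned ground truth summarizes the *noiseless* parameter contours
    with the same statistics the extractor computes (F0 family and temporal
    features share the extractor's scale; loudness truth is on the envelope
    scale; jitter/shimmer/HNR truth is the planted parameter itself).
    """
    fs = config.sample_rate
    hop = 0.010
    dur = config.clip_duration_s + rng.uniform(-0.3, 0.3)
    xg = lambda k: x.get(k, 0.0)

    base_st = hz_to_semitone(base_f0_hz) + 1.2 * xg("f0_mean")
    mod_depth = 1.3 * np.exp(0.25 * xg("f0_range") + 0.15 * xg("f0_sd_norm"))
    mod_freq = 1.2 * np.exp(0.2 * (xg("f0_rise_slope") + xg("f0_fall_slope")) / 2)
    declination = 0.8      # semitones/s downward within a segment
    amp = 0.22 * np.exp(0.35 * xg("loudness_mean"))
    rise_frac = float(np.clip(0.25 * np.exp(-0.3 * xg("loudness_rise_slope")), 0.08, 0.45))
    fall_frac = float(np.clip(0.25 * np.exp(-0.3 * xg("loudness_fall_slope")), 0.08, 0.45))
    jitter = 0.04 * np.exp(0.25 * xg("jitter_mean"))
    shimmer_db = 1.3 * np.exp(0.20 * xg("shimmer_mean"))
    hnr_db = 5.0 + 2.5 * xg("hnr_mean")
    seg_scale = np.exp(-0.30 * xg("voiced_segments_per_second"))
    pause_scale = np.exp(0.35 * xg("mean_unvoiced_segment_length"))

    # segment plan: voiced/pause alternation
    segs: list[tuple[float, float]] = []   # (start, length)
    t = rng.uniform(0.02, 0.10)
    pauses: list[float] = []
    while t < dur - 0.15:
        vlen = float(np.clip(rng.lognormal(np.log(0.30 * seg_scale), 0.25), 0.12, 1.2))
        vlen = min(vlen, dur - t - 0.01)
        if vlen < 0.12:
            break
        segs.append((t, vlen))
        plen = float(np.clip(rng.lognormal(np.log(0.20 * pause_scale), 0.30), 0.06, 1.0))
        if t + vlen + plen < dur - 0.12:
            pauses.append(plen)
        t += vlen + plen
    if not segs:
        segs = [(0.05, max(dur - 0.1, 0.12))]

    n_total = int(dur * fs)
    y = np.zeros(n_total)
    sigma_T = jitter / 1.1284          # E|dT|/T of iid normal perturbations
    sigma_A = shimmer_db / 1.1284

    truth_f0: list[np.ndarray] = []
    truth_env: list[np.ndarray] = []
    for (t0, vlen) in segs:
        phi0 = rng.uniform(0, 2 * np.pi)

        def f0_st_at(tau: float) -> float:
            return base_st + mod_depth * np.sin(2 * np.pi * mod_freq * tau + phi0) \
                   - declination * tau

        def env_at(tau: float) -> float:
            u = tau / vlen
            if u < rise_frac:
                r = u / rise_frac
            elif u > 1.0 - fall_frac:
                r = (1.0 - u) / fall_frac
            else:
                r = 1.0
            return amp * (0.35 + 0.65 * r)

        tau = 0.0
        pos = int(t0 * fs)
        voiced_samples: list[np.ndarray] = []
        while True:
            f_hz = 27.5 * 2.0 ** (f0_st_at(tau) / 12.0)
            T = (1.0 / f_hz) * (1.0 + sigma_T * rng.standard_normal())
            nsamp = max(int(round(T * fs)), 4)
            if tau + nsamp / fs > vlen:
                break
            nh = max(1, min(8, int(0.45 * fs / f_hz)))
            # pulse peak slightly inside the cycle (phase pi/8) so period
            # peaks are interior samples, not boundary-ambiguous
            theta = 2 * np.pi * np.arange(nsamp) / nsamp - np.pi / 8
            cyc = np.zeros(nsamp)
            for h in range(1, nh + 1):
                cyc += np.cos(h * theta) / h
            cyc /= np.max(cyc)
            a = env_at(tau) * 10.0 ** (sigma_A * rng.standard_normal() / 20.0)
            voiced_samples.append(a * cyc)
            tau += nsamp / fs
        if not voiced_samples:
            continue
        seg_wave = np.concatenate(voiced_samples)
        rms = float(np.sqrt(np.mean(seg_wave ** 2)))
        noise = rms * 10.0 ** (-hnr_db / 20.0) * rng.standard_normal(len(seg_wave))
        end = min(pos + len(seg_wave), n_total)
        y[pos:end] += (seg_wave + noise)[: end - pos]

        grid = np.arange(0.0, tau, hop)
        truth_f0.append(np.array([f0_st_at(g_) for g_ in grid]))
        truth_env.append(np.array([env_at(g_) for g_ in grid]))

    y += 5e-5 * rng.standard_normal(n_total)
    peak = np.max(np.abs(y))
    if peak > 0.99:
        y = y * (0.99 / peak)
    y = np.round(y * 32767.0) / 32767.0    # int16 grid: file and memory agree

    st_all = np.concatenate(truth_f0) if truth_f0 else np.array([])
    env_all = np.concatenate(truth_env) if truth_env else np.array([])
    truth = dict.fromkeys(ACOUSTIC_FEATURES, float("nan"))
    if len(st_all) >= 2:
        truth["f0_mean"] = float(st_all.mean())
        truth["f0_sd_norm"] = float(st_all.std(ddof=1) / st_all.mean())
        p20, p80 = np.percentile(st_all, [20, 80])
        truth["f0_range"] = float(p80 - p20)
        rise, fall, lrise, lfall = [], [], [], []
        for st_seg, env_seg in zip(truth_f0, truth_env):
            r, f = _monotone_run_slopes(st_seg, hop, _SEMITONE_TOL)
            rise += r
            fall += f
            r, f = _monotone_run_slopes(env_seg, hop, 0.02 * np.median(env_all))
            lrise += r
            lfall += f
        truth["f0_rise_slope"] = float(np.mean(rise)) if rise else float("nan")
        truth["f0_fall_slope"] = float(np.mean(fall)) if fall else float("nan")
        truth["loudness_rise_slope"] = float(np.mean(lrise)) if lrise else float("nan")
        truth["loudness_fall_slope"] = float(np.mean(lfall)) if lfall else float("nan")
    if len(env_all):
        truth["loudness_mean"] = float(env_all.mean())
    truth["jitter_mean"] = float(jitter)
    truth["shimmer_mean"] = float(shimmer_db)
    truth["hnr_mean"] = float(hnr_db)
    truth["voiced_segments_per_second"] = len(segs) / dur
    truth["mean_unvoiced_segment_length"] = float(np.mean(pauses)) if pauses else float("nan")

    return RenderedVoice(clip=AudioClip(samples=y, sample_rate=fs), truth=truth)


def render_keyboard_bin(config: SimulationConfig, x_form: dict[str, float],
                        x_content: dict[str, float], base_speed: float,
                        esm_ms: int, entry_id_start: int,
                        rng: np.random.Generator,
                        lexicon: Lexicon | None = None
                        ) -> tuple[list[dict], list[tuple], int]:
    """Entries and keystroke events for the hour around one survey.

    Returns (entry rows, keystroke event tuples, next entry id).  Entry rows
    carry the message text (used for writing-content extraction); keystroke
    tuples are (entry_id, key_class, press_ms, release_ms).
    """
    lexicon = lexicon or load_demo_lexicon()
    n_entries = 1 + rng.poisson(config.entries_per_bin_mean *
                                np.exp(0.25 * x_form.get("n_entries", 0.0)))
    speed = base_speed * np.exp(0.18 * x_form.get("typing_speed", 0.0))
    press_mean = 80.0 * np.exp(0.12 * x_form.get("avg_key_press_duration", 0.0))
    p_back = float(np.clip(config.backspace_prob *
                           np.exp(0.4 * x_form.get("backspaces_rel", 0.0)), 0.0, 0.45))

    entries: list[dict] = []
    events: list[tuple] = []
    eid = entry_id_start
    # entry starts stay clear of the +-30 min boundary
    starts = np.sort(rng.uniform(esm_ms - 29.0 * 60000, esm_ms + 29.0 * 60000,
                                 size=n_entries)).astype(np.int64)
    for start in starts:
        text, _ = render_transcript(config, x_content, "writing", rng, lexicon)
        n_pos = rng.poisson(config.pos_emoji_rate / max(n_entries, 1))
        n_neg = rng.poisson(config.neg_emoji_rate / max(n_entries, 1))
        if n_pos or n_neg:
            pos_pool = sorted(lexicon.pos_emojis)
            neg_pool = sorted(lexicon.neg_emojis)
            text += " " + " ".join(
                list(rng.choice(pos_pool, size=n_pos)) +
                list(rng.choice(neg_pool, size=n_neg)))
        n_char = len(text)
        n_back = int(rng.binomial(n_char, p_back))
        n_ev = n_char + n_back
        duration_ms = 1000.0 * n_char / speed
        gaps = rng.uniform(0.5, 1.5, size=max(n_ev - 1, 1))
        press = start + np.concatenate([[0.0], np.cumsum(gaps)])[:n_ev] \
            * (duration_ms / max(gaps[: n_ev - 1].sum(), 1e-9) if n_ev > 1 else 0.0)
        press = press.astype(np.int64)
        durs = np.clip(rng.normal(press_mean, 8.0, size=n_ev), 20.0, 250.0).astype(np.int64)
        release = press + durs
        is_back = np.zeros(n_ev, dtype=bool)
        if n_back:
            is_back[rng.choice(n_ev, size=n_back, replace=False)] = True
        for i in range(n_ev):
            events.append((eid, "backspace" if is_back[i] else "character",
                           int(press[i]), int(release[i])))
        entries.append({"entry_id": eid, "start_ms": int(start),
                        "message": text, "esm_ms": int(esm_ms)})
        eid += 1
    return entries, events, eid
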