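# whealsim

Modelling and morphological classification of skin wheals in chronic
spontaneous urticaria (CSU).

CSU produces transient skin eruptions (wheals) whose shapes — rings, broken
rings, coalescing maps, isolated disks, small dots — reflect the state of
the underlying pathophysiological network: histamine released from basophils
(`[H_B]`) and dermal mast cells (`[H_M]`), tissue-factor expression on the
vascular endothelium (`[TF]`), and coagulation factors leaking from blood
vessels (`[C]`). `whealsim` implements this network as a hierarchical
reaction–diffusion model on a 2D dermis sheet,

```
d[H_B]/dt = δ_B + γ_B [TF] χ_B (1 − g_B([H_B])) − μ_B [H_B]          on basophil sites
d[TF]/dt  = δ_T + f_T([H_B],[H_M]) (1 − g_T([H_B]+[H_M])) − μ_T [TF]
∂[C]/∂t   = D_C ∇²[C] + f_leak([TF]) − μ_C [C]
∂[H_M]/∂t = D_M ∇²[H_M] + δ_M + γ_M [C] χ_M (1 − g_M([H_M])) − μ_M [H_M]
```

with Hill-2 inhibition ratios `g(H) = α H² / (α₀ + H²)` (adenosine feedback
on histamine release and TF expression), saturating TF activation
`f_T = γ_T H / (γ_T0 + H)`, and a sigmoidal plasma-leakage switch
`f_leak = γ_C / (1 + e^{−β([TF] − T_sw)})` whose threshold `T_sw` sits in
the experimentally bracketed 1–3 ng/mL window of endothelial gap formation.
`χ_B, χ_M` are Heaviside indicators of finite histamine reservoirs: cells
release until their content is exhausted. The visible eruption is the
sigmoid `S_w([C]) = 1/(1+e^{−β_w([C]−A_r)})`, thresholded into a binary
wheal mask.

The package covers the full workflow around that model:

* `whealsim.model_functions` — the closed-form response functions;
* `whealsim.calibration` — least-squares estimation of the response
  parameters from dose–response tables and impedance (cell-index) traces;
* `whealsim.simulator` — the explicit operator-split integrator with
  depletable reservoirs, mass-balance ledger and snapshot series;
* `whealsim.classifier` — eruption-geometry (EGe) classification of mask
  series into two classes / five types (annular, broken-annular,
  geographic, circular, dot) via five key features KF1–KF5;
* `whealsim.efast` — extended Fourier Amplitude Sensitivity Test with a
  dummy-parameter significance gate;
* `whealsim.vote_stats` — inter-rater vote-counting reliabilities SB/SS,
  classifiable-rate summaries and the binomial tail P-value;
* `whealsim.synthetic` — seeded generators for every input class;
* `whealsim.presets` — calibrated pattern-regime presets and the
  (γ_M, μ_M, α_M) repertoire sweep;
* `whealsim` CLI — `simulate`, `classify`, `sweep`, `fit`, `efast`,
  `votes`, `generate`.

## Worked example

Simulate the annular regime, then classify the resulting mask series:

```
$ whealsim simulate --preset annular --seed 3 --out demo/run
wrote 12 snapshots to demo/run

$ whealsim classify --run-dir demo/run --out demo/cls
{"class": "boundary", "type": "annular", "evidence": {"kf1": 0.376,
 "kf2": 1.0, "kf3": 0.624, "kf4_merges": 1, "kf4_growth": 8.03,
 "kf5": false, "mean_diameter_cm": 3.67, "max_diameter_cm": 9.89}}
```

`kf1 = 0.376` is the annularity of the dominant wheal (hole area over
filled area — a ring, not a disk), `kf2 = 1` says its boundary is a single
closed arc, so the eruption is boundary-class, annular type.

Reliability statistics for a synthetic six-rater cohort of 105 samples with
92 unanimous votes:

```
$ whealsim generate --what votes --seed 1 --out demo/g
$ whealsim votes --matrix demo/g/votes.csv --p0 0.5 --out demo/v
{"classifiable": {"n_samples": 105, "n_classifiable": 92,
 "classifiable_rate_pct": 87.62, "nonqualifying_rate_pct": 0.0, ...},
 "type_frequencies": {"annular": 19, "broken-annular": 19, "geographic": 18,
 "circular": 18, "dot": 18}, "binomial_tail_pvalue": 3.99e-16}
```

87.6% of samples are classifiable at full concordance, and the binomial
tail P-value rejects a population classifiable rate of 50%.

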