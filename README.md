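# evireg — evidential-reasoning image registration

Aligning two images of the same scene — a reference *R* and a sensed *S* —
means estimating the planar projective transform *T* between them.
Different keypoint detectors (sparse route) or different similarity
measures (dense route) produce different, individually plausible estimates,
and committing to any single one bakes that choice's failure modes into the
result. `evireg` treats the choice itself as an uncertainty: the candidate
transforms T₁…T_Q form a frame of discernment, evidence for each candidate
is gathered on three information channels, and the evidence is fused with
belief-function combination rules into a single combined transform.

It is written for people analysing microscopy/histology or other
single-channel 2-D imagery who need registrations that degrade gracefully
when one detector or measure fails, and for anyone who wants a clean,
tested implementation of Dempster–Shafer / PCR6 combination applied to a
concrete estimation problem.

## The method in brief

For each candidate Tᵢ, the sensed image is warped into the reference frame
and compared with *R* by normalized cross-correlation on three channels:
gray intensities, Canny edge maps, and phase-angle reconstructions
(NCCᵢ⁽G⁾, NCCᵢ⁽E⁾, NCCᵢ⁽P⁾). Each channel yields a Bayesian basic belief
assignment over the candidates via the contrast stretch y = eˣ − 1:

    m_c(Tᵢ) = (e^{NCCᵢ} − 1) / Σⱼ (e^{NCCⱼ} − 1)

The three BBAs are combined — Dempster's rule m = m_G ⊕ m_E ⊕ m_P, or the
n-source PCR6 rule, which redistributes conflicting mass products back to
their contributors — and the combined transform is the mass-weighted
average in inverse space:

    T_c⁻¹ = Σᵢ m(Tᵢ) · Tᵢ⁻¹

Registration quality against a known ground truth T_true is scored by AAID
(average absolute intensity difference) between *R* and *R* warped by
T_true·T_c⁻¹ — zero exactly when T_c = T_true — plus a 5×5 spatial
partition of the same score. See `docs/methods.md` for assumptions,
parameter defaults and limitations.

## Worked example

Register a noisy synthetic pair (known mild projective motion, Gaussian
noise of variance 0.01) with the sparse route and PCR6 fusion:

```python
from evireg import EvidentialRegistration
from evireg.fixtures import scenario_suite

sc = [s for s in scenario_suite(0) if s.name == "hestain_like-proj-noisy"][0]
R, S, T_true = sc.replay()

res = EvidentialRegistration(R, S, mode="sparse", rule="pcr6").fit(seed=1)
print(res.summary())
print(f"AAID(R, R'_c) = {res.evaluate(R, T_true).aaid:.4f}")
for lab, rep in res.candidate_reports(R, T_true).items():
    print(f"  single-candidate AAID [{lab}]: {rep.aaid:.4f}")
```

Output:

```
Evidential registration results
================================================================
mode: sparse    rule: pcr6    candidates: 3

     candidate   NCC(G)   NCC(E)   NCC(P)      m_c
----------------------------------------------------
          sift   0.8940   0.3179   0.1614   0.3342
           orb   0.8774   0.3255   0.1812   0.3587
 censure-brief   0.8511   0.3123   0.1529   0.3070

combined transform T_c (row-vector convention):
   [   1.013798     0.033620     0.000067]
   [  -0.032045     1.004635    -0.000060]
   [  -0.569219    -8.269095     1.000000]

AAID(R, R'_c) = 0.0118
  single-candidate AAID [sift]: 0.0118
  single-candidate AAID [orb]: 0.0162
  single-candidate AAID [censure-brief]: 0.0203
```

Each row shows one candidate's three channel similarities and its mass in
the combined BBA. The fused transform matches the best single candidate
(AAID 0.0118) without knowing in advance which detector that would be —
the point of the method. On [0, 1] intensities an AAID of 0.01 corresponds
to ~2.5 gray levels of 8-bit residual per pixel.

The same chain is available from the shell:

```sh
evireg fixtures --suite default --seed 0 --outdir fixtures/
evireg fuse --ref fixtures/blobs-rigid10-ref.png --sen fixtures/blobs-rigid10-sen.png \
            --mode dense --rule pcr6 --out result.json --registered registered.png
evireg evaluate --ref fixtures/blobs-rigid10-ref.png \
                --t-true fixtures/blobs-rigid10-t_true.json \
                --t-est result.json --out report.json --heatmap aaid.png
```

(`evireg sparse` and `evireg dense` run a single candidate generator and
write the transform JSON; `evireg fuse --dump-bbas` exports every BBA.)

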