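# lcmvar

Somatic-variant analysis for laser-microdissected endometrial gland trios:
rule-based somatic calling from per-site read counts, amplicon-deep-sequencing
(ADS) verification, and driver-gene burden statistics, plus a synthetic-data
generator that emulates WGA/LCM sequencing noise so the whole pipeline is
testable end to end.

## The problem

Deep infiltrating endometriosis lesions are built from endometrial-like
glands outside the uterus. Whether the epithelial cells of those glands carry
somatic mutations — and in particular mutations in cancer driver genes — is a
question about rare cells: a single gland isolated by laser-capture
microdissection (LCM) yields so little DNA that it must be whole-genome
amplified (WGA) before targeted sequencing, which distorts allele fractions
and creates replicate-private artifacts. Conventional tumor–normal callers
tuned to bulk tissue find nothing in this material, so the analysis falls
back to two explicit count rules applied per site against the patient's
blood reference:

* **presence** — a variant is present in a sample when at least 2 reads
  carry the alternate allele;
* **absence** — a variant is positively absent only when coverage is
  strictly >20× and *no* non-reference base is seen there.

A variant is **somatic** when present in tissue and positively absent from
blood; if blood absence cannot be established the call is *indeterminate*,
never silently dropped. Candidate variants are then verified by amplicon
deep re-sequencing (>2000×) over every available replicate: detected in ≥1
replicate → confirmed; detected in none → excluded as a WGA/PCR artifact.

## The burden statistic

With a capture panel of $G = G_d + G_n$ genes ($G_d$ drivers, $G_n$
non-drivers) and $k_d$, $k_n$ somatic variants observed per class in one
tissue compartment, the per-gene mutation chance of a class is $k/G$ and
class enrichment is assessed with Fisher's exact test on

$$\begin{pmatrix} k_d & k_n \\ G_d & G_n \end{pmatrix}$$

using the minimum-likelihood two-sided rule: with margins fixed, the
p-value sums the hypergeometric probabilities of every table no more likely
than the observed one (computed here by log-space enumeration; an
independent brute-force enumerator and `scipy.stats.fisher_exact` back it in
the tests). The ectopic-vs-eutopic comparison tests the two compartments'
class counts $\begin{pmatrix} k_d^{ect} & k_n^{ect} \\ k_d^{eu} & k_n^{eu} \end{pmatrix}$ the same way.

## Worked example

The package bundles a 13-patient deep-endometriosis cohort table (59 somatic
variants with HGVS descriptions and gnomAD frequencies; genomic coordinates
are deterministic placeholders, and the 1296-gene panel with its 85-gene
driver list is a labelled synthetic reconstruction that reproduces the
cohort's class sizes). Running

```
python analysis/04_burden.py
```

prints:

```
59 somatic variants: 24 ectopic-only, 31 eutopic-only, 4 in both tissues
ECT: chance of driver-gene mutation 0.059 (5/85) vs non-driver 0.016 (19/1211), enrichment p = 0.0199
EU: chance of driver-gene mutation 0.024 (2/85) vs non-driver 0.024 (29/1211), enrichment p = 1.0000
ectopic vs eutopic class counts: p = 0.2197
genes mutated in >1 patient: ['ATRX', 'DNAH7', 'RYR1']; recurrent identical variants: 0
ADS verification of tissue-shared variants: DYSF confirmed, HERC2 excluded, JAK2 excluded, TROAP excluded
```

In ectopic lesions driver genes are mutated significantly more often per
gene than non-drivers (p = 0.0199); in eutopic endometrium the two classes
are mutated at the same rate; the difference between compartments does not
itself reach significance (p = 0.2197). Three of the four variants seen in
both tissues fail deep re-sequencing — they were amplification artifacts —
and no identical variant recurs across patients.

The simulation arm runs the same machinery on generated data with known
truth:

```
python analysis/01_simulate.py   # 13 trios at 159x, low-VAF somatic truth
python analysis/02_call.py       # rule-based calling + recall vs truth
python analysis/03_verify.py     # simulated ADS confirms true calls,
                                 # excludes replicate-private artifacts
```

The same stages are available as a CLI (`lcmvar simulate|call|verify|burden|
report|fixture-run`); `lcmvar fixture-run` re-asserts every headline number
above and exits non-zero on any mismatch.

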