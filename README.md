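# oligoplex

Design and validation toolkit for **multiplex PCR / TaqMan-qPCR
species-identification panels** and for **multi-target artificial positive
controls (APCs)** — synthetic DNA constructs that carry the priming sites of
every assay in a panel so a single clonable plasmid serves as the positive
control for all of them.

The package ships a worked five-species panel for stored-product booklice
(*Liposcelis* spp.), identified by species-specific primers and hydrolysis
probes on the mitochondrial CO1 barcoding locus, and reproduces that panel's
published properties end to end: per-oligo thermodynamics, in-silico PCR
specificity, APC construct layout, fluorophore channel assignment and
qPCR standard-curve statistics.

## Who it is for

Diagnostics developers building multiplex endpoint-PCR or probe-based qPCR
assays who need to (1) screen *given* oligos for self/cross compatibility,
(2) predict amplicons and verify exclusivity against near-neighbor species,
(3) lay out a synthetic positive-control insert whose product sizes are
chosen at design time, and (4) analyze dilution-series Ct data.

## The models at its core

**Oligo thermodynamics.** Melting temperatures come from unified
nearest-neighbor ΔH/ΔS parameters with the Owczarzy monovalent/divalent salt
correction (defaults: 50 nM oligo, 50 mM Na⁺, 1.5 mM Mg²⁺, 0.6 mM dNTP).
Self- and cross-dimer propensity is scored as the maximum number of
Watson–Crick pairs over all ungapped antiparallel alignments (the "any"
score), with a 3'-anchored variant for primer-dimer risk ("3'" score), and
hairpins by an exhaustive single stem-loop model
(stacking sum + loop-closure penalty).

**In-silico PCR.** Binding sites are exact or mismatch-bounded matches with
a perfect 3' clamp (default 3 nt); an amplicon spans both primer footprints,
so its length is `reverse_end − forward_start + 1`. Multiplex simulation
crosses every assay with every template, including cross-assay
forward/reverse pairings, and a virtual gel flags bands closer than a
minimum separation (default 20 bp).

**APC design.** Each target contributes a block: outer (endpoint) forward
primer, inner (qPCR) forward primer, probe site, inner reverse and outer
reverse (reverse elements embedded as reverse complements). Spacer DNA is
solved so every pair amplifies its requested size *exactly*; spacers are
GC-balanced, screened against every panel oligo's 3'-terminal 8-mer and
any 12 nt match, and each block carries a unique barcode so every APC
amplicon is sequence-identifiable against its genomic counterpart.

**Standard curves.** For a 10-fold dilution series, Ct is linear in
log₁₀(amount): an OLS fit gives slope *Y*, *R*², and efficiency
*Ex* = 10^(−1/Y) − 1 (Y = −3.32 ⇒ perfect doubling).

## Worked example

```python
import oligoplex as ox

panel = ox.load_default_panel()          # 5 targets, 20 primers, 5 probes
cfg = ox.load_apc_config()               # requested APC product sizes

construct, report = ox.design_apc(panel, cfg["sizes"], seed=1)
print(len(construct), report.passed)
# 1272 True

tpl = construct.template
for assay in panel:
    ep = ox.predict_amplicons(assay.endpoint_pair, tpl)[0]
    qp = ox.predict_amplicons(assay.qpcr_pair, tpl)[0]
    print(f"{assay.target:18s} endpoint {ep.length:3d} bp  qPCR {qp.length:3d} bp")
# L_brunnea          endpoint 140 bp  qPCR 140 bp
# L_bostrychophila   endpoint 184 bp  qPCR  96 bp
# L_decolor          endpoint  99 bp  qPCR  99 bp
# L_obscura          endpoint 322 bp  qPCR  72 bp
# L_pearmani         endpoint 241 bp  qPCR  67 bp

for s in ox.load_default_dilutions():
    if s.kit == "rotor_gene":
        fit = ox.fit_standard_curve(s)
        print(f"{s.channel:8s} Y={fit.slope:+.2f} R2={fit.r2:.3f} Ex={fit.efficiency:.2f}")
# orange   Y=-3.31 R2=1.000 Ex=1.01
# yellow   Y=-3.29 R2=1.000 Ex=1.01
# red      Y=-3.37 R2=1.000 Ex=0.98
# crimson  Y=-3.37 R2=1.000 Ex=0.98
# green    Y=-3.35 R2=1.000 Ex=0.99
```

The construct is 1272 bp of adapters-free insert; every primer pair returns
exactly its designed size, every probe sits strictly between its primers,
and the standard-curve refits of the shipped dilution table land on the
published slope/efficiency values. A command-line interface wraps the same
operations (`oligoplex panel check`, `oligoplex ispcr`, `oligoplex apc
design|verify`, `oligoplex curve fit`, `oligoplex fixtures make`).

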