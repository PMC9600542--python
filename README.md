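# pvsignal

Disproportionality-based signal detection for spontaneous adverse-event
reporting databases, with a synthetic report generator for method
validation.

## The problem

Pharmacovigilance databases collect individual case safety reports
(ICSRs): one spontaneous report per patient, each listing one or more
suspected drugs, one or more adverse-event preferred terms (PTs, the
specific event labels of a MedDRA-like hierarchy), and demographics.
Signal detection asks whether a drug–event pair is reported *more often
than expected* given how often the drug and the event are reported
overall. The motivating use case is screening a biologic asthma therapy
(an IgE-blocking monoclonal antibody) for ear-and-labyrinth and
eosinophil-related disorders against the other biologics in its class —
but the pipeline is generic.

For each pair, reports are cross-classified into the classic 2×2 table
(a: drug and event; b: drug only; c: event only; d: neither), and three
disproportionality statistics are computed:

- **PRR** = [a/(a+b)] / [c/(c+d)] — proportional reporting ratio,
- **ROR** = (a/b) / (c/d) — reporting odds ratio,
- **IC** = log₂((a + 0.5) / (E + 0.5)), E = (a+b)(a+c)/n — the shrinkage
  information component, with its 95% credibility lower bound
  **IC025** = IC − 3.3(a+0.5)^−1/2 − 2.4(a+0.5)^−3/2
  (a gamma-posterior Monte-Carlo percentile is available as a
  cross-check).

A pair is flagged as a **signal** when it has at least 3 co-reports,
PRR ≥ 2, ROR ≥ 2 and IC025 above 0 — a statistical reporting
association, not a demonstrated causal adverse reaction. Signals are
rolled up from PT to primary system organ class (SOC), summarized as
subset share tables and demographic breakdowns, and visualized as a
squarified treemap (tile area = signals per SOC, color = reports per
SOC on a log scale).

Because real extracts of global pharmacovigilance databases are
access-restricted, the package ships a synthetic ICSR generator with
*planted* drug–event relative reporting ratios and known ground truth,
so sensitivity and false-flag rates of the whole pipeline are
measurable.

## Worked example

```python
from pvsignal import default_config, generate, screen
from pvsignal.hierarchy import rollup_by_soc, subset_shares, eosinophil_filter

dataset, truth = generate(default_config(n_reports=50_000, seed=42))
results = screen(dataset, ["omalizumab"])
signals = [r for r in results if r.is_signal]
print(f"{len(results)} pairs screened, {len(signals)} signals")

rollup = rollup_by_soc(results, dataset.dictionary)
for s in rollup.summaries[:3]:
    print(f"{s.soc}: {s.n_signals} signals / {s.n_reports} reports")

ear = [r for r in signals
       if dataset.dictionary.primary_soc(r.event_pt) == "Ear and labyrinth disorders"]
for row in subset_shares(ear)[:3]:
    r = next(x for x in ear if x.event_pt == row.event_pt)
    print(f"{row.event_pt}: {row.n_reports} ({row.share_pct}%) "
          f"PRR={r.prr:.2f} ROR={r.ror:.2f} IC025={r.ic025:.2f}")
```

prints

```
53 pairs screened, 19 signals
Ear and labyrinth disorders: 11 signals / 3784 reports
Blood and lymphatic system disorders: 2 signals / 1108 reports
Investigations: 2 signals / 1193 reports
Ear pain: 1202 (31.77%) PRR=3.69 ROR=3.78 IC025=0.24
Ear discomfort: 665 (17.57%) PRR=3.31 ROR=3.36 IC025=0.19
Otorrhoea: 443 (11.71%) PRR=13.58 ROR=13.74 IC025=0.28
```

The generator planted elevated ear/eosinophil reporting ratios for
omalizumab; the screen recovers them: 11 of the 19 signals are ear
disorders, and `eosinophil_filter([r.event_pt for r in signals])`
returns the 8 planted eosinophil PTs. Note the comparator universe here
is only biologics users, so roughly half of all reports list the target
drug — this dilutes PRR/IC below the planted ratios, exactly as a
class-restricted comparator does on real data.

The same run as a shell pipeline:

```sh
pvsignal run --config examples/demo.yaml --outdir out/
```

writes `results.csv`, `soc_summary.csv`, `demographics.csv`,
`subset_shares.csv`, `treemap.svg` and `truth_eval.csv` (planted-pair
sensitivity and null false-flag rate). `pvsignal simulate / screen /
summarize / treemap` expose the stages individually.

## Layout

| module | contents |
|---|---|
| `pvsignal.model` | ICSR/dictionary domain types, CSV dialects |
| `pvsignal.synth` | synthetic database generator + ground truth |
| `pvsignal.contingency` | 2×2 table construction over report sets |
| `pvsignal.disproportionality` | PRR, ROR, IC, IC025, signal criterion |
| `pvsignal.hierarchy` | SOC rollups, shares, demographics, eosinophil filter |
| `pvsignal.treemap` | squarified layout + SVG rendering |
| `pvsignal.pipeline`, `pvsignal.cli` | end-to-end orchestration, `pvsignal` CLI |

See `docs/methods.md` for the statistical model, generator assumptions
and numerical choices.
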