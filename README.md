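# jadersig

Disproportionality signal detection for JADER-style spontaneous
adverse-event report tables, built for pharmacovigilance analyses of
nutrition-related adverse reactions (decreased appetite, weight loss
and taste disturbance), and applicable to any Preferred-Term query set.

Spontaneous reporting databases such as Japan's JADER ship as linked
CSV tables: a drug table (one row per drug per report, with a
suspected / concomitant / interacting role) and a reaction table (one
row per adverse event, named by a MedDRA Preferred Term, PT), joined
by a case identification number. `jadersig` turns those dumps into
signal tables:

1. read the tables under a configurable dialect (packaged defaults for
   the CP932 Japanese export and a plain ASCII form), keeping one
   report version per case and only suspected-drug records;
2. link into the **pair universe** of unique (case, suspected drug,
   PT) triples — each suspected drug in a multi-drug report counts as
   a separate adverse-reaction report;
3. for each (drug, PT), form the 2×2 table (a, b, c, d) over the pair
   universe and compute the Reporting Odds Ratio
   ROR = ad/bc with its 95% Wald CI
   exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)), the Proportional Reporting
   Ratio PRR = [a/(a+b)]/[c/(c+d)], and the Pearson χ² (Yates-corrected
   by default);
4. flag a **signal** only when the CI lower bound > 1 *and*
   PRR ≥ 2, χ² ≥ 4, n = a ≥ 3;
5. classify signal drugs by Japanese therapeutic category (codes
   beginning "42", antineoplastics, are excluded), find drugs
   signalling across multiple PTs, and cross-tabulate package-insert
   annotation status.

A synthetic report generator (`jadersig.simulate`) emits
pipeline-compatible tables with planted associations of known odds
ratio plus an exact truth registry, so every stage — and the operating
characteristics of the composite criterion — is verifiable without
downloading the real database. See `docs/methods.md` for the model,
assumptions and design choices.

## Worked example

Generate a synthetic population (2,000 cases, 20 drugs, the seven
nutrition-related target PTs, two planted associations — OR 8 for
drug02 × Decreased appetite, OR 6 for drug05 × Dysgeusia) and run the
full pipeline:

```sh
jadersig simulate --preset default --seed 7 --out demo/data
jadersig run --drug demo/data/drug.csv --reac demo/data/reac.csv \
             --dialect ascii --out demo/out
```

The run prints the manifest (abridged):

```json
{
  "rows_read": {"drug": 3453, "reac": 2250},
  "rows_after_dedup": {"drug": 3145, "reac": 2045},
  "cases_after_dedup": {"drug": 2000, "reac": 2000},
  "suspected_records": 1700,
  "n_pairs": 1676,
  "n_target_pairs": 171,
  "candidates_tested": 71,
  "signals_total": 1
}
```

Reading it: 3,453 drug rows collapse to 2,000 cases after removing
duplicate report versions; 1,700 suspected-drug records link with the
reaction rows into 1,676 unique (case, drug, PT) pairs, 171 of which
name a target PT; 71 (drug, PT) candidates were scored and one met the
composite criterion. The top of `demo/out/signals.tsv`:

```
drug_name  pt_name             a   b    c   d     ror     ci_low  ci_high  prr     chi2    n   signal
drug02     Decreased appetite  17  137  18  1504  10.37   5.224   20.58    9.334   61.71   17  True
drug00     Decreased appetite  5   442  30  1199  0.4521  0.1743  1.173    0.4582  2.194   5   False
```

The planted drug02 association is recovered (ROR 10.4, CI 5.2–20.6,
all criteria met); the weaker Dysgeusia plant drew only 3 target
reports at this seed and stays below threshold — exactly the
behaviour the criterion's n ≥ 3 / χ² ≥ 4 floors are designed to
enforce. `demo/data/truth.json` holds the generator's registry for
comparison.

For a real JADER snapshot, point `--drug`/`--reac` at the PMDA CSV
export (the default `japanese` dialect maps 識別番号 / 報告回数 /
医薬品の関与 / 医薬品（一般名） / 有害事象 and the
被疑薬 / 併用薬 / 相互作用 role vocabulary), supply your PT query CSV
(the packaged default is the seven-PT nutrition set, e.g.
Decreased appetite 10061428, Taste disorder 10082490) and a
drug → therapeutic-category CSV. Reproducing published whole-database
counts additionally requires the matching database snapshot (e.g. the
May-2025 release) and a MedDRA-consistent PT mapping.

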