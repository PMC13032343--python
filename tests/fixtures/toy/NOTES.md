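# Toy fixture: hand-derived flow

Twelve cases (C01–C12), ASCII dialect. C01 is reported twice (versions
1 and 2, identical content); C08 has only a concomitant drug; C07 lists
the same drug under two `drug_seq` entries; C05 carries an interacting
drug.

## Stage counts

| stage                         | drug table | reac table |
|-------------------------------|------------|------------|
| rows read                     | 18         | 15         |
| rows after dedup (latest ver) | 16         | 14         |
| cases after dedup             | 12         | 12         |
| suspected records             | 13         | —          |

Suspected drug sets per case after dedup:
C01 {alpha}, C02 {alpha}, C03 {alpha, gamma}, C04 {beta}, C05 {beta},
C06 {gamma}, C07 {alpha} (two rows collapse), C08 {} (concomitant only),
C09 {delta}, C10 {alpha}, C11 {alpha}, C12 {gamma}.

## Pair universe (unique case × suspected drug × PT): 14 pairs

C01 (alpha, decreased appetite); C02 (alpha, decreased appetite),
(alpha, nausea); C03 (alpha, dysgeusia), (gamma, dysgeusia);
C04 (beta, nausea); C05 (beta, decreased appetite);
C06 (gamma, nausea); C07 (alpha, decreased appetite);
C09 (delta, dysgeusia); C10 (alpha, decreased appetite);
C11 (alpha, decreased appetite); C12 (gamma, decreased appetite),
(gamma, dysgeusia).

C08 contributes nothing (no suspected drug).

Target pairs under the default PT set: 11 (Decreased appetite 7 over
drugs {alpha×5, beta×1, gamma×1}; Dysgeusia 4 over {alpha×1, gamma×2,
delta×1}); Nausea is not queried.

## Hand contingency tables (N = 14)

alpha × Decreased appetite: a=5, b=2, c=2, d=5.
ROR = 25/4 = 6.25; ln ROR = 1.832581…; SE = √(1/5+1/2+1/2+1/5) = √1.4;
CI = exp(1.832581 ∓ 1.96·1.183216) = (0.61476…, 63.5438…).
PRR = (5/7)/(2/7) = 2.5.
χ² (plain) = 14·21²/(7·7·7·7) = 6174/2401 = 2.571428…;
χ² (Yates) = 14·(21−7)²/2401 = 2744/2401 = 1.142857…
Verdict: criterion a fails (CI lower bound < 1) → no signal.

gamma × Dysgeusia: a=2, b=2, c=2, d=8.
ROR = 16/4 = 4.0; PRR = (2/4)/(2/10) = 2.5;
χ² (plain) = 14·12²/(4·10·4·10) = 2016/1600 = 1.26;
χ² (Yates) = 14·(12−7)²/1600 = 350/1600 = 0.21875.
Verdict: no signal (n = 2 < 3 among other failures).

No (drug, PT) candidate meets the composite criterion, so the toy run
yields zero signals; candidates tested = 3 (Decreased appetite) +
3 (Dysgeusia) = 6.
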