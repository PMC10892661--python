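"""k-mer naive-Bayes classification of simulated pmoA amplicons.

Builds a synthetic reference database, simulates reads from a known
genotype mixture with 1% sequencing error, classifies them and compares the
recovered composition with the truth.
"""

from sipseek import make_reference_db, simulate_amplicon_reads
from sipseek.community import relative_abundance
from sipseek.taxonomy import assignment_counts, classify_reads, train_classifier

truth = {"Methylocystis": 26.93, "RPC-2": 50.40, "Methylosarcina": 19.43,
         "pmoA-2": 1.51, "USC-gamma": 0.61}

db = make_reference_db(seed=7)
model = train_classifier(db, k=8)
reads = simulate_amplicon_reads(truth, db, depth=20_000, error_rate=0.01, seed=8)
calls = classify_reads(reads, model, n_bootstrap=100, confidence_cutoff=80, seed=9)

accuracy = (calls["genotype"].to_numpy() == reads.true_genotypes).mean()
recovered = relative_abundance(assignment_counts(calls))
print(f"reads: {len(reads)}; assignment accuracy: {accuracy:.2%}")
print(f"{'genotype':<15}{'truth %':>10}{'recovered %':>14}")
total = sum(truth.values())
for g, v in sorted(truth.items(), key=lambda kv: -kv[1]):
    print(f"{g:<15}{100 * v / total:>10.2f}{recovered[g]:>14.2f}")

# Recovered percentages track the generating mixture to within multinomial
# sampling noise; accuracy stays near 100% because the genotypes sit at
# ~15% sequence divergence, far above the 1% read error.
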