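"""Compute speech-fluency measures from an utterance-annotated transcript.

Generates a 50-utterance transcript with naturally occurring disfluencies,
then prints speaking rate (all utterances), articulation rate (fluent
utterances only), the percentage of disfluent utterances, and the
distribution of disfluency annotations by type. Speaking rate is always
the lower of the two rates because disfluent pauses count against it.
"""

from tractofluency import (
    FluencyResponseSet,
    articulation_rate,
    disfluency_stats,
    generate_transcript,
    speaking_rate,
    verbal_fluency_score,
)

transcript = generate_transcript(n_utterances=50, seed=3)
stats = disfluency_stats(transcript)

print(f"speaking rate      : {speaking_rate(transcript):.2f} syllables/s")
print(f"articulation rate  : {articulation_rate(transcript):.2f} syllables/s")
print(f"percent disfluent  : {stats['percent_disfluent']:.1f}% of utterances")
print("disfluency types   :",
      {t: round(v, 1) for t, v in stats["type_distribution"].items() if v})

# verbal fluency: three category criteria; subcategory words ("birds") are
# not counted when specific exemplars were also produced
sets = [
    FluencyResponseSet("semantic", "animals", ["raven", "pigeon", "birds", "dog", "raven"],
                       subcategory_exemplars={"birds": {"raven", "pigeon"}}),
    FluencyResponseSet("semantic", "fruits", ["apple", "pear", "plum"]),
    FluencyResponseSet("semantic", "vehicles", ["car", "bus"]),
]
print(f"semantic fluency   : {verbal_fluency_score(sets)} correct unique responses "
      "(3 + 3 + 2; 'birds' and the repeated 'raven' are not counted)")
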