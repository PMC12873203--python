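Annotation guidelines (condensed): Montreal behavior classification of
Crohn's disease from clinical narrative text.

Classify each note by the most severe disease behavior it documents:
  B1 - non-stricturing, non-penetrating: no luminal narrowing and no
       fistulizing complication is described.
  B2 - stricturing: any stricture, stenosis, luminal narrowing or bowel
       obstruction attributable to Crohn's disease.
  B3 - penetrating: any fistula, sinus tract, abscess, phlegmon or
       perforation attributable to Crohn's disease.

Perianal disease is an independent yes/no modifier: any complication in the
perianal region (perianal fistula or abscess, anal fissure, seton in place,
perianal skin disease) sets it to "yes" regardless of the B class.

Rules of interpretation:
  - Behavior is cumulative over the disease history: a resolved or surgically
    treated complication still counts ("history of fistula" is B3).
  - Explicitly negated findings do not count ("no evidence of stricture").
  - Complications of other organ systems (e.g. carotid stenosis, aortic
    stenosis) are not Crohn's behavior and must be ignored.
  - A perianal fistula or perianal abscess is simultaneously penetrating
    (B3) disease and perianal disease.

Report exactly: behavior (B1, B2 or B3), the derived dichotomy (B2/B3 vs
Not B2/B3) and perianal (yes or no).
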