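{
  "comment": "Editable Crohn's disease complication terminology. Two routes: surface string patterns and concept entries with synonym lists. 'implies_behavior' marks perianal complications that also constitute penetrating (B3) disease.",
  "string_entries": [
    {"pattern": "stricture", "category": "B2"},
    {"pattern": "strictures", "category": "B2"},
    {"pattern": "stricturing", "category": "B2"},
    {"pattern": "stenosis", "category": "B2"},
    {"pattern": "stenoses", "category": "B2"},
    {"pattern": "stenotic", "category": "B2"},
    {"pattern": "narrowing", "category": "B2"},
    {"pattern": "obstruction", "category": "B2"},
    {"pattern": "obstructions", "category": "B2"},
    {"pattern": "fistula", "category": "B3"},
    {"pattern": "fistulas", "category": "B3"},
    {"pattern": "fistulae", "category": "B3"},
    {"pattern": "fistulizing", "category": "B3"},
    {"pattern": "sinus tract", "category": "B3"},
    {"pattern": "abscess", "category": "B3"},
    {"pattern": "abscesses", "category": "B3"},
    {"pattern": "perforation", "category": "B3"},
    {"pattern": "perforations", "category": "B3"},
    {"pattern": "phlegmon", "category": "B3"},
    {"pattern": "perianal fistula", "category": "perianal", "implies_behavior": "B3"},
    {"pattern": "perianal fistulas", "category": "perianal", "implies_behavior": "B3"},
    {"pattern": "perianal abscess", "category": "perianal", "implies_behavior": "B3"},
    {"pattern": "perirectal abscess", "category": "perianal", "implies_behavior": "B3"},
    {"pattern": "anal fissure", "category": "perianal"},
    {"pattern": "anal fissures", "category": "perianal"},
    {"pattern": "seton", "category": "perianal"},
    {"pattern": "setons", "category": "perianal"},
    {"pattern": "perianal disease", "category": "perianal"}
  ],
  "concepts": [
    {
      "concept_id": "CDP0001",
      "category": "B2",
      "preferred": "intestinal stricture",
      "synonyms": [
        "luminal narrowing",
        "anastomotic stricture",
        "ileal stenosis",
        "bowel obstruction",
        "small bowel obstruction",
        "high-grade obstruction"
      ]
    },
    {
      "concept_id": "CDP0002",
      "category": "B3",
      "preferred": "penetrating complication",
      "synonyms": [
        "enterocutaneous fistula",
        "enteroenteric fistula",
        "enterovesical fistula",
        "rectovaginal fistula",
        "intra-abdominal abscess",
        "pelvic abscess",
        "bowel perforation",
        "free perforation"
      ]
    },
    {
      "concept_id": "CDP0003",
      "category": "perianal",
      "preferred": "perianal disease",
      "synonyms": [
        "perianal fistulizing disease",
        "anorectal abscess",
        "perianal sepsis",
        "anal skin tags"
      ],
      "implies_behavior_synonyms": [
        "perianal fistulizing disease",
        "anorectal abscess",
        "perianal sepsis"
      ]
    }
  ],
  "abbreviations": {
    "RVF": "rectovaginal fistula",
    "ECF": "enterocutaneous fistula",
    "SBO": "small bowel obstruction",
    "IBD": "inflammatory bowel disease",
    "CD": "Crohn's disease",
    "MRI": "magnetic resonance imaging",
    "CT": "computed tomography"
  }
}
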