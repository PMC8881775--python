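{
  "description": "Small open demo lexicon (synthetic, Dutch-flavoured) with the 11 word categories used by the content-feature extractor. Entries ending in '*' are wildcard stems matched by prefix. This is NOT the proprietary LIWC 2015 dictionary; it only mirrors its category structure.",
  "categories": {
    "i": ["ik", "mij", "mijn", "me", "mezelf", "ikzelf", "mijzelf"],
    "we": ["wij", "we", "ons", "onze", "onszelf", "wijzelf"],
    "you": ["jij", "je", "jou", "jouw", "jullie", "u", "uw", "jezelf"],
    "negate": ["niet", "geen", "nooit", "niets", "niks", "nee", "noch", "nergens", "zonder", "neen"],
    "posemo": ["blij*", "leuk*", "fijn*", "goed", "geweldig*", "mooi*", "gelukkig*", "super", "tof*", "prettig*", "lach*", "geniet*", "genoten", "liefde", "lief", "dankbaar*", "trots*", "plezier*", "tevreden", "geslaagd", "gezellig*", "vrolijk*", "top"],
    "negemo": ["slecht*", "vervelend*", "rot", "rotdag", "naar", "ellendig*", "afschuwelijk*", "verschrikkelijk*", "pijnlijk*", "jammer", "teleurgesteld*", "teleurstell*", "negatief*", "akelig*", "erg", "balen", "stom*"],
    "anx": ["bang*", "angst*", "nerveus*", "zenuwachtig*", "gespannen", "onzeker*", "paniek*", "vrees*", "bezorgd*", "zorgen", "eng"],
    "anger": ["boos*", "kwaad", "woede*", "woedend*", "geirriteerd*", "irritatie*", "razend*", "haat*", "frustratie*", "gefrustreerd*", "ergernis*"],
    "sad": ["verdriet*", "droevig*", "somber*", "huil*", "treurig*", "depressie*", "rouw*", "eenzaam*", "wanhopig*", "neerslachtig*"],
    "certain": ["altijd", "zeker*", "absoluut", "helemaal", "iedereen", "alles", "volledig*", "totaal", "compleet", "echt", "nooit"],
    "swear": ["verdomme", "shit", "fuck*", "kut", "godver*", "damn", "verdorie", "klote*"]
  },
  "pos_emojis": ["😊", "😂", "😁", "❤️", "👍", ":)", ":-)", ":D", ";-)"],
  "neg_emojis": ["😢", "😞", "😠", "💔", ":(", ":-("]
}
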