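# Synthetic demo topic vocabulary: topics of interest and the keywords
# that map onto them. The taxonomy mirrors the survey categories used to
# elicit participant interests (technology, health, lifestyle, science,
# hobbies, other); keyword lists are illustrative stand-ins for an entity
# linker and are written for testing.
topics:
  - social networks
  - technological devices
  - video games
  - nutrition
  - physical wellbeing
  - mental wellbeing
  - interpersonal relationships
  - activism
  - religion and spirituality
  - economy
  - politics and justice
  - philosophy
  - biology
  - sports
  - movies and tv
  - music
  - literature
  - current news
  - languages
  - cultures of the world
keywords:
  instagram: [social networks]
  twitter: [social networks]
  tiktok: [social networks]
  hashtag: [social networks]
  smartphone: [technological devices]
  laptop: [technological devices]
  console: [technological devices, video games]
  playstation: [video games, technological devices]
  nintendo: [video games]
  gamer: [video games]
  diet: [nutrition]
  calories: [nutrition]
  vitamins: [nutrition]
  recipe: [nutrition]
  food: [nutrition]
  gym: [physical wellbeing, sports]
  yoga: [physical wellbeing]
  exercise: [physical wellbeing]
  therapy: [mental wellbeing]
  mindfulness: [mental wellbeing]
  anxiety: [mental wellbeing]
  recovery: [mental wellbeing]
  friendship: [interpersonal relationships]
  family: [interpersonal relationships]
  protest: [activism]
  volunteering: [activism]
  prayer: [religion and spirituality]
  meditation: [religion and spirituality, mental wellbeing]
  inflation: [economy]
  markets: [economy]
  election: [politics and justice]
  rights: [politics and justice]
  ethics: [philosophy]
  stoicism: [philosophy]
  genetics: [biology]
  ecosystem: [biology]
  football: [sports]
  tennis: [sports]
  marathon: [sports, physical wellbeing]
  cinema: [movies and tv]
  series: [movies and tv]
  concert: [music]
  playlist: [music]
  guitar: [music]
  novel: [literature]
  poetry: [literature]
  headlines: [current news]
  breaking news: [current news]
  spanish: [languages]
  english: [languages]
  travel: [cultures of the world]
  traditions: [cultures of the world]
subcategory_topics:
  applications and social media: [social networks]
  technological devices: [technological devices]
  videogames: [video games]
  nutrition: [nutrition]
  physical wellbeing: [physical wellbeing]
  mental wellbeing: [mental wellbeing]
  interpersonal relationships: [interpersonal relationships]
  activism: [activism]
  religion and spirituality: [religion and spirituality]
  economy: [economy]
  politics and justice: [politics and justice]
  philosophy: [philosophy]
  biology: [biology]
  sports: [sports]
  movies and tv: [movies and tv]
  music: [music]
  literature: [literature]
  current news: [current news]
  languages: [languages]
  cultures of the world: [cultures of the world]
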