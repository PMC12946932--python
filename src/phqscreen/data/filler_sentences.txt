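# Neutral filler sentences for the synthetic post generator.
# Must contain no symptom-ontology term and no temporal-frequency modifier phrase;
# tests verify this against the packaged ontology.
the bus was late again this morning
my neighbour is repainting his fence this week
we watched an old film after dinner
the coffee shop around the corner changed its menu
it rained for most of the afternoon
i finally returned the library books
the garden needs weeding before the weekend
traffic on the highway was heavier than usual
my sister called about the holiday plans
the printer at work jammed twice today
we are thinking about repotting the ferns
the grocery store was out of oat milk
a parcel arrived for the previous tenant
the kettle takes ages to boil in this flat
my laptop installed updates during lunch
the football match went to extra time
the landlord fixed the dripping tap at last
i swapped the winter duvet for the summer one
the bakery sells out of rye bread by noon
our street is getting new lamp posts
the cat from next door visits our balcony
i mislaid my umbrella somewhere on campus
the museum has a new exhibit about lighthouses
the recycling truck comes on thursdays now
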