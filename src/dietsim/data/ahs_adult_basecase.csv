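field,unit,total,core,discretionary,discretionary_foods,discretionary_beverages
grams_food_weight,g,3337.7,2652.2,685.5,178.8,513.6
energy,kj,8697.8,5654.0,3043.8,2173.5,841.9
protein,g,91.0,75.6,15.4,13.5,0.9
total_fat,g,73.8,47.4,26.4,26.1,0.3
sfa,g,27.7,16.1,11.6,11.4,0.2
mufa,g,0,0,0,0,0
pufa,g,0,0,0,0,0
carbohydrate,g,225.9,145.6,80.4,56.3,23.6
total_sugars,g,102.9,51.3,51.5,30.7,20.6
added_sugars,g,50.6,6.7,43.9,25.2,18.6
free_sugars,g,57.8,10.8,47.1,26.8,20.2
sodium,mg,2430.5,1567.1,863.5,796.8,61.6
alcohol,g,14.4,0.0,14.4,0.0,14.4
fiber,g,22.9,19.9,3.0,2.9,0.1
vitamin_a_re,ug,851.8,732.2,119.6,107.3,7.9
thiamine,mg,1.5,1.2,0.3,0.3,0.0
riboflavin,mg,1.9,1.5,0.4,0.3,0.1
niacin_equivalents,mg,41.4,33.5,7.9,6.2,1.4
dietary_folate_equivalents,ug,609.9,529.0,80.9,74.1,4.8
vitamin_b6,mg,1.5,1.1,0.4,0.2,0.2
vitamin_b12,ug,4.5,3.8,0.7,0.6,0.1
vitamin_c,mg,102.3,86.1,16.2,3.9,12.1
vitamin_e,mg,10.5,7.8,2.7,2.6,0.1
calcium,mg,804.6,677.6,127.0,93.4,25.1
iodine,ug,172.3,146.5,25.8,17.9,6.5
iron,mg,11.1,9.0,2.2,1.7,0.4
magnesium,mg,338.7,274.2,64.5,40.6,21.4
phosphorus,mg,1466.9,1137.3,329.6,259.8,58.6
potassium,mg,2912.5,2345.5,567.0,413.2,141.4
selenium,ug,91.0,75.4,15.6,12.9,2.5
zinc,mg,11.0,9.3,1.7,1.5,0.1
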